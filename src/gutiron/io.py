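"""File-format adapters: plate-reader CSV, calibration CSV, chromatogram
CSV/mzML, FASTA, GFF3-like TSV, YAML config and JSON reports.

CSV/TSV files are comma- (resp. tab-) separated UTF-8 with a mandatory
header row.  Genomic coordinates are 1-based inclusive both on disk and
in memory.  Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .growth import GrowthCurve
from .operon import GeneLocus, ProteinSeq
from .quant import CalibrationPoint, Chromatogram, Scan

__all__ = [
    "write_growth_csv",
    "read_growth_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "write_chromatogram_csv",
    "read_chromatogram_csv",
    "read_chromatogram_mzml",
    "write_fasta",
    "read_fasta",
    "write_gff_tsv",
    "read_gff_tsv",
    "load_yaml_config",
    "write_json_report",
]

GFF_COLUMNS = ["seqid", "source", "type", "start", "end", "score", "strand", "attributes"]


# -- plate-reader OD time series --------------------------------------------

def write_growth_csv(path, curves: Sequence[GrowthCurve]) -> None:
    rows = [
        {"time_h": t, "well": c.replicate_id, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od)
    ]
    pd.DataFrame(rows, columns=["time_h", "well", "od600"]).to_csv(path, index=False)


def read_growth_csv(path) -> list[GrowthCurve]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["time_h", "well", "od600"], path)
    curves = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                times=grp["time_h"].to_numpy(float),
                od=grp["od600"].to_numpy(float),
                replicate_id=str(well),
            )
        )
    return curves


# -- calibration standards ---------------------------------------------------

def write_calibration_csv(path, points: Sequence[CalibrationPoint]) -> None:
    pd.DataFrame(
        [{"level": p.level, "signal": p.signal} for p in points],
        columns=["level", "signal"],
    ).to_csv(path, index=False)


def read_calibration_csv(path) -> list[CalibrationPoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["level", "signal"], path)
    return [
        CalibrationPoint(level=float(r.level), signal=float(r.signal))
        for r in df.itertuples()
    ]


# -- chromatograms -----------------------------------------------------------

def write_chromatogram_csv(path, chrom: Chromatogram) -> None:
    rows = [
        {"scan_time_min": s.time, "mz": mz, "intensity": inten}
        for s in chrom.scans
        for mz, inten in zip(s.mz, s.intensity)
    ]
    # default float formatting is the shortest round-trip repr, so
    # read(write(x)) reproduces the arrays bit-exactly
    pd.DataFrame(rows, columns=["scan_time_min", "mz", "intensity"]).to_csv(path, index=False)


def read_chromatogram_csv(path) -> Chromatogram:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["scan_time_min", "mz", "intensity"], path)
    scans = []
    for t, grp in df.groupby("scan_time_min", sort=True):
        scans.append(
            Scan(
                time=float(t),
                mz=grp["mz"].to_numpy(float),
                intensity=grp["intensity"].to_numpy(float),
            )
        )
    return Chromatogram(scans=scans)


def read_chromatogram_mzml(path) -> Chromatogram:
    """Read MS1 scans from an mzML file (via pyteomics) into a Chromatogram."""
    from pyteomics import mzml as _mzml

    scans = []
    with _mzml.MzML(str(path)) as reader:
        for spec in reader:
            if spec.get("ms level", 1) != 1:
                continue
            scan_info = spec["scanList"]["scan"][0]
            t = float(scan_info["scan start time"])
            scans.append(
                Scan(
                    time=t,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                )
            )
    scans.sort(key=lambda s: s.time)
    return Chromatogram(scans=scans)


# -- sequences and gene coordinates ------------------------------------------

def write_fasta(path, seqs: Sequence[ProteinSeq]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[ProteinSeq]:
    return [
        ProteinSeq(id=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_gff_tsv(path, loci: Sequence[GeneLocus], source: str = "gutiron") -> None:
    rows = [
        {
            "seqid": x.contig,
            "source": source,
            "type": "gene",
            "start": x.start,
            "end": x.end,
            "score": ".",
            "strand": x.strand,
            "attributes": f"gene={x.gene}",
        }
        for x in loci
    ]
    pd.DataFrame(rows, columns=GFF_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gff_tsv(path) -> list[GeneLocus]:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, GFF_COLUMNS, path)
    loci = []
    for i, r in enumerate(df.itertuples(), start=2):  # header is line 1
        attrs = dict(
            kv.split("=", 1) for kv in str(r.attributes).split(";") if "=" in kv
        )
        if "gene" not in attrs:
            raise ValueError(f"{path}, line {i}: missing gene= attribute")
        try:
            locus = GeneLocus(
                gene=attrs["gene"],
                contig=str(r.seqid),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
        loci.append(locus)
    return loci


# -- config and reports -------------------------------------------------------

def load_yaml_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def write_json_report(path, report: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
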
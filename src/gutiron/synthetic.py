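"""Synthetic inputs for every pipeline stage.

This module emulates the wet-lab and database inputs the analysis
consumes, with the statistical structure the downstream methods assume:

* Gompertz-shaped OD600 curves with additive Gaussian read noise;
* linear AA / LC-MS calibration series with multiplicative signal noise;
* Q-TOF chromatograms as dense scan grids carrying Gaussian elution
  peaks at the heme (616.17) and PPIX (563.26) m/z channels;
* protein families at a controlled percent identity to an ancestor
  (uniform substitutions, no indels, so identity is exact by count);
* genome layouts carrying the 6-gene hmu operon with controlled
  presence/absence/copy-number/order.

All generators are deterministic given a seed.  Default condition
parameters mirror the rich-medium triplicate fits (A = 1.46 au,
mu_m = 0.260 au/h, lam = 4.94 h) and the measured conversion factor of
6.0 µg DNA·mL⁻¹·au⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .growth import GompertzParams, GrowthCurve, gompertz_od
from .operon import AA_ALPHABET, HMU_GENES, GeneLocus, ProteinSeq
from .quant import (
    HEME_MZ,
    IRON_MOLAR_MASS,
    PPIX_MZ,
    CalibrationPoint,
    Chromatogram,
    Scan,
)

__all__ = [
    "SimConfig",
    "PeakSpec",
    "CultureBundle",
    "DEFAULT_GROWTH_PARAMS",
    "DEFAULT_DNA_PER_OD",
    "AA_LEVELS_PPM",
    "PORPHYRIN_LEVELS_UM",
    "gen_growth_curve",
    "gen_calibration_series",
    "gen_chromatogram",
    "gen_protein_family",
    "gen_genome_layout",
    "gen_culture_dataset",
]

#: Rich-medium triplicate Gompertz fit (asymptote au, rate au/h, lag h).
DEFAULT_GROWTH_PARAMS = GompertzParams(A=1.46, mu_m=0.260, lam=4.94)

#: Measured DNA-per-OD conversion factor, µg DNA·mL⁻¹·au⁻¹.
DEFAULT_DNA_PER_OD = 6.0

#: AA iron standards, ppm (instrument working range 0.1–4 ppm).
AA_LEVELS_PPM = (0.1, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0)

#: Porphyrin standards, µM (serial dilution 0.25–6 µM).
PORPHYRIN_LEVELS_UM = (0.25, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)

# Instrument response constants for the forward model (signal per level).
AA_SLOPE_PER_PPM = 0.080  # absorbance / ppm Fe
MS_SLOPE_HEME = 5.0e4  # counts·min / µM
MS_SLOPE_PPIX = 7.0e4  # counts·min / µM
HEME_RT_MIN = 4.4
PPIX_RT_MIN = 5.2
PEAK_SIGMA_MIN = 0.1
CHROM_DURATION_MIN = 8.0


@dataclass(frozen=True)
class SimConfig:
    """Noise and sampling configuration shared by the generators.

    ``noise_sd_od`` is additive (au), ``noise_rel_signal`` multiplicative
    (fraction), ``mz_sigma`` the per-scan mass-measurement jitter (Da) —
    kept well inside the ±0.02 Da EIC window — and ``scan_interval_min``
    the chromatogram sampling step (≤ σ/5 for percent-accurate areas).
    """

    seed: int = 0
    noise_sd_od: float = 0.01
    noise_rel_signal: float = 0.01
    scan_interval_min: float = 0.02
    mz_sigma: float = 0.003

    def __post_init__(self) -> None:
        for name in ("noise_sd_od", "noise_rel_signal", "mz_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (self.scan_interval_min > 0):
            raise ValueError("scan interval must be positive")

    def zero_noise(self) -> "SimConfig":
        """Copy of this config with every noise scale set to 0."""
        return replace(self, noise_sd_od=0.0, noise_rel_signal=0.0, mz_sigma=0.0)


@dataclass(frozen=True)
class PeakSpec:
    """A Gaussian elution peak at a fixed m/z channel."""

    mz: float
    retention_time: float  # minutes
    height: float  # counts at apex
    sigma_rt: float  # minutes

    def __post_init__(self) -> None:
        if not (self.mz > 0):
            raise ValueError(f"m/z must be positive, got {self.mz}")
        if not (self.sigma_rt > 0):
            raise ValueError(f"sigma_rt must be positive, got {self.sigma_rt}")
        if self.height < 0:
            raise ValueError(f"height must be non-negative, got {self.height}")

    @property
    def area(self) -> float:
        """Closed-form Gaussian area h·σ·√(2π), counts·min."""
        return self.height * self.sigma_rt * math.sqrt(2.0 * math.pi)


def gen_growth_curve(
    params: GompertzParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "rep1",
) -> GrowthCurve:
    """Gompertz OD series plus i.i.d. Gaussian read noise, floored at 0."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    od = gompertz_od(params, times)
    od = np.atleast_1d(od) + rng.normal(0.0, noise_sd, size=times.size) if noise_sd else np.atleast_1d(od)
    return GrowthCurve(times=times, od=np.maximum(od, 0.0), replicate_id=replicate_id)


def gen_calibration_series(
    slope: float,
    levels: Sequence[float],
    rel_noise: float = 0.0,
    seed: int = 0,
) -> list[CalibrationPoint]:
    """Linear standard series signal_i = slope·level_i·(1 + ε_i)."""
    if not (slope > 0):
        raise ValueError(f"slope must be positive, got {slope}")
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("standard levels must be non-negative")
    if rel_noise < 0:
        raise ValueError("rel_noise must be non-negative")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, rel_noise, size=levels.size) if rel_noise else np.zeros(levels.size)
    signals = slope * levels * (1.0 + eps)
    return [CalibrationPoint(level=float(l), signal=float(s)) for l, s in zip(levels, signals)]


def gen_chromatogram(
    peaks: Sequence[PeakSpec], duration: float, config: SimConfig
) -> Chromatogram:
    """Dense-grid Q-TOF chromatogram carrying the requested Gaussian peaks.

    Each scan holds one (m/z, intensity) entry per distinct m/z channel;
    co-eluting peaks on the same channel sum.  The duration must cover
    every peak out to ±4σ, otherwise truncated areas would silently bias
    quantification.
    """
    for p in peaks:
        if p.retention_time - 4 * p.sigma_rt < 0 or p.retention_time + 4 * p.sigma_rt > duration:
            raise ValueError(
                f"duration {duration} min does not cover peak at rt={p.retention_time} "
                f"± 4σ ({4 * p.sigma_rt} min)"
            )
    rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, duration + config.scan_interval_min / 2, config.scan_interval_min)
    channels = sorted({p.mz for p in peaks})
    scans = []
    for t in times:
        mzs = np.empty(len(channels))
        intens = np.empty(len(channels))
        for c, mz in enumerate(channels):
            signal = sum(
                p.height * math.exp(-((t - p.retention_time) ** 2) / (2 * p.sigma_rt**2))
                for p in peaks
                if p.mz == mz
            )
            if config.noise_rel_signal:
                signal *= 1.0 + rng.normal(0.0, config.noise_rel_signal)
            jitter = rng.normal(0.0, config.mz_sigma) if config.mz_sigma else 0.0
            mzs[c] = mz + jitter
            intens[c] = max(signal, 0.0)
        scans.append(Scan(time=float(t), mz=mzs, intensity=intens))
    return Chromatogram(scans=scans)


def gen_protein_family(
    length: int, target_identity: float, n_seqs: int, seed: int = 0
) -> list[ProteinSeq]:
    """A random ancestor plus derived sequences at a fixed percent identity.

    Exactly round(length × (100 − target)/100) positions of each derived
    sequence are substituted (uniformly chosen sites, uniformly chosen
    non-identical residues), so realized identity to the ancestor equals
    the target up to the rounding granularity of one site.  No indels.
    The ancestor is the first element of the returned list.
    """
    if length < 10:
        raise ValueError(f"sequence length must be ≥ 10, got {length}")
    if not (0 < target_identity <= 100):
        raise ValueError(f"target identity must be in (0, 100], got {target_identity}")
    if n_seqs < 1:
        raise ValueError("need at least one derived sequence")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    ancestor = rng.choice(alphabet, size=length)
    n_sub = round(length * (100.0 - target_identity) / 100.0)
    out = [ProteinSeq(id="ancestor", residues="".join(ancestor))]
    for i in range(n_seqs):
        derived = ancestor.copy()
        sites = rng.choice(length, size=n_sub, replace=False)
        for s in sites:
            others = alphabet[alphabet != ancestor[s]]
            derived[s] = rng.choice(others)
        out.append(ProteinSeq(id=f"derived_{i + 1}", residues="".join(derived)))
    return out


# Representative hmu gene lengths (bp), in operon order.
_GENE_LENGTHS = {
    "hmuY": 630,
    "hmuR": 2200,
    "hmuS": 3900,
    "hmuT": 900,
    "hmuU": 750,
    "hmuV": 430,
}
_DISTANT_OFFSET_BP = 1_000_000  # where duplicated copies land


def gen_genome_layout(
    pattern: str,
    gap_bp: int = 500,
    contig: str = "contig1",
    shuffle: bool = False,
    seed: int = 0,
) -> list[GeneLocus]:
    """Lay out hmu gene loci for a 6-character {0,1,2} conservation pattern.

    Genes scored '1' are placed colinearly (hmuY..hmuV order) with
    ``gap_bp`` intergenic spacing; genes scored '2' additionally get a
    second copy at a distant locus (1 Mb downstream); '0' genes are
    skipped.  ``shuffle`` permutes the cluster's gene order (a synteny-
    breaking rearrangement) while keeping the coordinates compact.
    Coordinates are 1-based inclusive on the forward strand.
    """
    if len(pattern) != 6 or any(c not in "012" for c in pattern):
        raise ValueError(f"pattern must be 6 chars over {{0,1,2}}, got {pattern!r}")
    cluster_genes = [g for g, c in zip(HMU_GENES, pattern) if c in "12"]
    duplicated = [g for g, c in zip(HMU_GENES, pattern) if c == "2"]
    if shuffle:
        rng = np.random.default_rng(seed)
        order = list(cluster_genes)
        while len(order) > 1 and order == cluster_genes:
            rng.shuffle(order)
        cluster_genes = order
    loci: list[GeneLocus] = []
    pos = 1
    for g in cluster_genes:
        end = pos + _GENE_LENGTHS[g] - 1
        loci.append(GeneLocus(gene=g, contig=contig, start=pos, end=end))
        pos = end + 1 + gap_bp
    dup_pos = pos + _DISTANT_OFFSET_BP
    for g in duplicated:
        end = dup_pos + _GENE_LENGTHS[g] - 1
        loci.append(GeneLocus(gene=g, contig=contig, start=dup_pos, end=end))
        dup_pos = end + 1 + gap_bp
    return loci


@dataclass
class CultureBundle:
    """Everything measured for one growth condition, plus the ground truth.

    ``true_values`` are the per-µg-DNA loads (pmol/µg) the forward model
    encoded; the quantification pipeline should recover them from the raw
    signals.  ``ms_peaks`` records the elution windows the generator used
    (retention time and width per analyte), which downstream integration
    needs just as an analyst would read them off the standards.  MS
    dilutions are per analyte — the porphyrin concentrate is injected
    neat for trace analytes (PPIX) and diluted for abundant ones (heme),
    as an analyst would, and each analyte's EIC channel is recorded at
    its own injection dilution.
    """

    condition: str
    growth_curve: GrowthCurve
    dna_ug_per_ml: float
    aa_calibration: list[CalibrationPoint]
    aa_signal: float
    aa_dilution: float
    aa_extract_volume_ml: float
    porphyrin_calibration: Mapping[str, list[CalibrationPoint]]
    chromatogram: Chromatogram
    ms_peaks: Mapping[str, PeakSpec]
    ms_dilutions: Mapping[str, float]
    ms_extract_volume_ml: float
    culture_volume_ml: float
    true_values: Mapping[str, float]


# Bench-protocol volume bookkeeping: each analytical subsample represents
# 10 mL of pooled culture; the iron subsample stays at 1 mL and is diluted
# 2x for AA, while porphyrins are SPE-concentrated into 0.1 mL with heme
# injected at a 25x dilution and PPIX injected neat.
CULTURE_VOLUME_ML = 10.0
AA_EXTRACT_ML = 1.0
AA_DILUTION = 2.0
MS_EXTRACT_ML = 0.1
MS_DILUTIONS = {"heme": 25.0, "ppix": 1.0}


def gen_culture_dataset(
    condition: str,
    true_values: Mapping[str, float],
    config: Optional[SimConfig] = None,
    growth_params: GompertzParams = DEFAULT_GROWTH_PARAMS,
    dna_per_od: float = DEFAULT_DNA_PER_OD,
    dna_ug_per_ml: Optional[float] = None,
) -> CultureBundle:
    """Forward-simulate one culture through every measurement channel.

    ``true_values`` holds per-µg-DNA loads in pmol/µg with keys
    ``total_iron``, ``heme`` and ``ppix``.  Each instrument channel
    responds linearly (AA absorbance per ppm Fe; EIC area per µM
    porphyrin, with peak heights chosen so the Gaussian closed-form area
    matches the target response), so at zero noise the quantification
    pipeline inverts this model exactly (up to EIC quadrature error,
    < 0.1 %).  The DNA yield defaults to stationary-phase OD times the
    DNA-per-OD factor but can be pinned with ``dna_ug_per_ml``.
    """
    config = config or SimConfig()
    if any(v < 0 for v in true_values.values()):
        raise ValueError("true per-DNA loads must be non-negative")
    rng_seeds = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in rng_seeds]

    times = np.arange(0.0, 30.5, 0.5)
    curve = gen_growth_curve(
        growth_params, times, noise_sd=config.noise_sd_od, seed=seeds[0], replicate_id=condition
    )
    if dna_ug_per_ml is None:
        od_stationary = gompertz_od(growth_params, float(times[-1]))
        dna = od_stationary * dna_per_od  # µg/mL, from the measured conversion factor
    else:
        dna = float(dna_ug_per_ml)

    def conc_per_culture(pmol_per_ug: float) -> float:
        return pmol_per_ug * dna * 1e-3  # nmol/mL culture

    # AA channel: total iron
    aa_cal = gen_calibration_series(
        AA_SLOPE_PER_PPM, AA_LEVELS_PPM, config.noise_rel_signal, seed=seeds[1]
    )
    fe_um_injected = (
        conc_per_culture(true_values["total_iron"])
        * CULTURE_VOLUME_ML / AA_EXTRACT_ML / AA_DILUTION
    )
    noise = np.random.default_rng(seeds[2])
    aa_signal = AA_SLOPE_PER_PPM * fe_um_injected * IRON_MOLAR_MASS / 1000.0
    if config.noise_rel_signal:
        aa_signal *= 1.0 + noise.normal(0.0, config.noise_rel_signal)

    # LC-MS channel: heme and PPIX from the concentrated porphyrin extract
    porph_cal = {
        "heme": gen_calibration_series(
            MS_SLOPE_HEME, PORPHYRIN_LEVELS_UM, config.noise_rel_signal, seed=seeds[3]
        ),
        "ppix": gen_calibration_series(
            MS_SLOPE_PPIX, PORPHYRIN_LEVELS_UM, config.noise_rel_signal, seed=seeds[4]
        ),
    }
    sqrt2pi = math.sqrt(2.0 * math.pi)
    specs = {}
    for analyte, mz, slope, rt in (
        ("heme", HEME_MZ, MS_SLOPE_HEME, HEME_RT_MIN),
        ("ppix", PPIX_MZ, MS_SLOPE_PPIX, PPIX_RT_MIN),
    ):
        um_injected = (
            conc_per_culture(true_values[analyte])
            * CULTURE_VOLUME_ML / MS_EXTRACT_ML / MS_DILUTIONS[analyte]
        )
        specs[analyte] = PeakSpec(
            mz=mz,
            retention_time=rt,
            height=slope * um_injected / (PEAK_SIGMA_MIN * sqrt2pi),
            sigma_rt=PEAK_SIGMA_MIN,
        )
    chrom = gen_chromatogram(
        [specs["heme"], specs["ppix"]],
        CHROM_DURATION_MIN,
        replace(config, seed=seeds[5]),
    )

    return CultureBundle(
        condition=condition,
        growth_curve=curve,
        dna_ug_per_ml=dna,
        aa_calibration=aa_cal,
        aa_signal=float(max(aa_signal, 0.0)),
        aa_dilution=AA_DILUTION,
        aa_extract_volume_ml=AA_EXTRACT_ML,
        porphyrin_calibration=porph_cal,
        chromatogram=chrom,
        ms_peaks=specs,
        ms_dilutions=dict(MS_DILUTIONS),
        ms_extract_volume_ml=MS_EXTRACT_ML,
        culture_volume_ml=CULTURE_VOLUME_ML,
        true_values=dict(true_values),
    )
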
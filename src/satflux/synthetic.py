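"""Synthetic-data generation for every pipeline input.

Two families of generators live here:

* **MRS**: complex ³¹P free-induction decays of skeletal muscle (PCr, Pi and
  the three ATP resonances as mixed Gaussian/Lorentzian lines), paired
  control/γATP-saturated acquisitions under two-site exchange, and
  inversion-recovery magnetization series — all with ground truth recorded
  alongside so that recovery by the processing/fitting/quantification stages
  can be tested without any real acquisition.

* **Expression**: a two-group probe-set × sample abundance matrix with
  planted fold changes and planted enriched functional categories, plus the
  probe→gene annotation (with a 3′ rank) and gene→category assignments.

Exchange model
--------------
Saturation of γATP drives the observed pool (Pi or PCr) to the two-site
steady state of the longitudinal Bloch–McConnell equations: with intrinsic
relaxation time T1 and forward rate constant kf,

    1/T1obs = 1/T1 + kf,     M_sat = M0 · T1obs/T1,

so the fractional saturation-transfer effect is ΔM/M0 = kf · T1obs =
kf/(kf + 1/T1), always in [0, 1). Inversion recovery under continued γATP
saturation relaxes as A1·[1 − A2·exp(−t/T1obs)] with A1 = M_sat and A2 = 2
for perfect inversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .processing import FID
from .quantify import InversionRecoverySeries

__all__ = [
    "PeakSpec",
    "ExchangeSpec",
    "SimulationConfig",
    "ExpressionSimSpec",
    "ExpressionSimResult",
    "DEFAULT_SHIFTS_PPM",
    "default_muscle_peaks",
    "simulate_fid",
    "simulate_saturation_pair",
    "simulate_inversion_recovery",
    "simulate_expression_dataset",
]

_LN2 = np.log(2.0)

#: Conventional ³¹P chemical shifts of resting skeletal muscle, referenced to
#: PCr = 0 ppm. γATP sits at −2.4 ppm; the others are standard muscle values.
DEFAULT_SHIFTS_PPM = {
    "PCr": 0.0,
    "Pi": 4.9,
    "gammaATP": -2.4,
    "alphaATP": -7.5,
    "betaATP": -16.0,
}

VALID_LABELS = frozenset(DEFAULT_SHIFTS_PPM)


@dataclass(frozen=True)
class PeakSpec:
    """One resonance of the simulated spectrum.

    ``amplitude`` is the frequency-domain peak height in arbitrary
    magnetization units; ``fwhm_hz`` the full width at half maximum;
    ``gauss_fraction`` the Gaussian share of the pseudo-Voigt lineshape.
    """

    label: str
    center_ppm: float
    amplitude: float
    fwhm_hz: float
    gauss_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValidationError(
                f"label: {self.label!r} is not one of {sorted(VALID_LABELS)}"
            )
        if not self.amplitude >= 0:
            raise ValidationError("amplitude: must be >= 0")
        if not self.fwhm_hz > 0:
            raise ValidationError("fwhm_hz: must be > 0")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValidationError("gauss_fraction: must be in [0, 1]")


@dataclass(frozen=True)
class ExchangeSpec:
    """Two-site exchange parameters for one observed pool (Pi or PCr).

    ``m0`` is the equilibrium magnetization used as the amplitude scale of
    inversion-recovery series; ``t1_intrinsic`` the intrinsic longitudinal
    relaxation time (s); ``kf`` the forward pseudo-first-order rate constant
    (s⁻¹) of the pool → γATP reaction.
    """

    m0: float
    t1_intrinsic: float
    kf: float

    def __post_init__(self) -> None:
        if not self.m0 > 0:
            raise ValidationError("m0: must be > 0")
        if not self.t1_intrinsic > 0:
            raise ValidationError("t1_intrinsic: must be > 0")
        if not self.kf >= 0:
            raise ValidationError("kf: must be >= 0")

    @property
    def t1obs(self) -> float:
        """Apparent T1 under partner saturation: 1/T1obs = 1/T1 + kf."""
        return 1.0 / (1.0 / self.t1_intrinsic + self.kf)

    @property
    def dm_over_m0(self) -> float:
        """Steady-state fractional saturation-transfer effect, kf·T1obs."""
        return self.kf * self.t1obs

    @property
    def saturation_factor(self) -> float:
        """M_sat/M0 = T1obs/T1 = 1 − ΔM/M0."""
        return self.t1obs / self.t1_intrinsic

    @classmethod
    def from_observed(cls, m0: float, t1obs: float, kf: float) -> "ExchangeSpec":
        """Build from the *observed* T1 (the quantity a study reports)."""
        if not t1obs > 0:
            raise ValidationError("t1obs: must be > 0")
        if kf >= 1.0 / t1obs:
            raise ValidationError("kf: must be < 1/t1obs for a positive intrinsic T1")
        return cls(m0=m0, t1_intrinsic=1.0 / (1.0 / t1obs - kf), kf=kf)


def default_muscle_peaks(gauss_fraction: float = 0.0) -> list[PeakSpec]:
    """A realistic resting-muscle ³¹P peak set (amplitudes in arbitrary units).

    PCr dominates; Pi is small; the three ATP resonances are intermediate.
    Lines default to pure Lorentzian (in vivo ³¹P lines are
    Lorentzian-dominated); pass ``gauss_fraction`` for mixed shapes.
    """
    spec = [
        ("PCr", 10.0, 12.0),
        ("Pi", 1.2, 15.0),
        ("gammaATP", 2.2, 18.0),
        ("alphaATP", 2.2, 18.0),
        ("betaATP", 1.8, 22.0),
    ]
    return [
        PeakSpec(lb, DEFAULT_SHIFTS_PPM[lb], amp, w, gauss_fraction)
        for lb, amp, w in spec
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one acquisition.

    ``noise_sd`` is the standard deviation of the complex circular Gaussian
    noise added per FID point; ``ir_noise_sd`` (if set) the noise on
    inversion-recovery magnetization values, which live on the fitted-area
    scale rather than the per-point scale. ``inversion_efficiency`` is the
    A2 factor of the recovery model (2 = perfect inversion).
    """

    spectrometer_freq_mhz: float = 162.1
    n_points: int = 4000
    sweep_width_hz: float = 10000.0
    noise_sd: float = 0.0
    seed: int = 0
    peaks: tuple[PeakSpec, ...] = field(default_factory=lambda: tuple(default_muscle_peaks()))
    exchange: Mapping[str, ExchangeSpec] = field(default_factory=dict)
    inversion_efficiency: float = 2.0
    ir_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if not self.spectrometer_freq_mhz > 0:
            raise ValidationError("spectrometer_freq_mhz: must be > 0")
        if self.n_points < 2:
            raise ValidationError("n_points: must be >= 2")
        if not self.sweep_width_hz > 0:
            raise ValidationError("sweep_width_hz: must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be >= 0")
        if self.ir_noise_sd is not None and self.ir_noise_sd < 0:
            raise ValidationError("ir_noise_sd: must be >= 0")
        labels = [p.label for p in self.peaks]
        if len(set(labels)) != len(labels):
            raise ValidationError("peaks: labels must be unique within a spectrum spec")
        object.__setattr__(self, "peaks", tuple(self.peaks))
        for pool in self.exchange:
            if pool not in ("Pi", "PCr"):
                raise ValidationError(f"exchange: observed pool must be Pi or PCr, got {pool!r}")
            if pool not in labels:
                raise ValidationError(f"exchange: pool {pool!r} has no peak in the spectrum")

    @property
    def dwell_time(self) -> float:
        return 1.0 / self.sweep_width_hz

    def peak(self, label: str) -> PeakSpec:
        for p in self.peaks:
            if p.label == label:
                return p
        raise KeyError(label)


def _fid_signal(config: SimulationConfig, scale: Mapping[str, float]) -> np.ndarray:
    """Noiseless sum of damped complex sinusoids, one per peak.

    Each peak contributes a Lorentzian (exponential decay, prefactor A·π·w)
    and a Gaussian (Gaussian decay, prefactor A·w·sqrt(π/ln2)) component so
    that the half-line Fourier transform has height A and FWHM w.
    """
    t = np.arange(config.n_points) * config.dwell_time
    signal = np.zeros(config.n_points, dtype=complex)
    for p in config.peaks:
        amp = p.amplitude * scale.get(p.label, 1.0)
        if amp == 0.0:
            continue
        f0 = p.center_ppm * config.spectrometer_freq_mhz  # ppm -> Hz
        w = p.fwhm_hz
        osc = np.exp(2j * np.pi * f0 * t)
        env = (1.0 - p.gauss_fraction) * amp * np.pi * w * np.exp(-np.pi * w * t)
        if p.gauss_fraction > 0.0:
            env = env + p.gauss_fraction * amp * w * np.sqrt(np.pi / _LN2) * np.exp(
                -((np.pi * w * t) ** 2) / (4.0 * _LN2)
            )
        signal += env * osc
    return signal


def _add_noise(signal: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return signal
    noise = rng.normal(scale=sd, size=(signal.size, 2))
    return signal + noise[:, 0] + 1j * noise[:, 1]


def _make_fid(config: SimulationConfig, signal: np.ndarray, truth: dict) -> FID:
    return FID(
        signal,
        dwell_time=config.dwell_time,
        spectrometer_freq_mhz=config.spectrometer_freq_mhz,
        metadata={"truth": truth, "seed": config.seed},
    )


def simulate_fid(config: SimulationConfig) -> FID:
    """Simulate a single (unsaturated) acquisition.

    Deterministic for a fixed seed; the ground-truth peak list is stored in
    ``metadata['truth']``.
    """
    rng = np.random.default_rng(config.seed)
    signal = _add_noise(_fid_signal(config, {}), config.noise_sd, rng)
    truth = {"peaks": [vars(p) | {} for p in config.peaks]}
    return _make_fid(config, signal, truth)


def simulate_saturation_pair(config: SimulationConfig) -> tuple[FID, FID]:
    """Simulate a control / γATP-saturated acquisition pair.

    The control member is an unperturbed spectrum (the mirror-saturation
    control is modeled as having no effect — ideal asymmetric control, no
    spillover). In the saturated member each observed pool's amplitude is
    scaled to its two-site steady state M0·T1obs/T1 and the γATP peak is
    removed. Noise draws for the two members come from one seeded stream.
    """
    if not config.exchange:
        raise ConfigurationError(
            "exchange: a saturation pair needs an ExchangeSpec for the observed pool(s)"
        )
    rng = np.random.default_rng(config.seed)
    control = _add_noise(_fid_signal(config, {}), config.noise_sd, rng)
    scale = {pool: ex.saturation_factor for pool, ex in config.exchange.items()}
    scale["gammaATP"] = 0.0
    saturated = _add_noise(_fid_signal(config, scale), config.noise_sd, rng)
    truth = {
        "peaks": [vars(p) | {} for p in config.peaks],
        "exchange": {
            pool: {
                "kf": ex.kf,
                "t1_intrinsic": ex.t1_intrinsic,
                "t1obs": ex.t1obs,
                "dm_over_m0": ex.dm_over_m0,
            }
            for pool, ex in config.exchange.items()
        },
    }
    return _make_fid(config, control, truth), _make_fid(config, saturated, truth)


def simulate_inversion_recovery(
    config: SimulationConfig, inversion_times: Sequence[float]
) -> dict[str, InversionRecoverySeries]:
    """Simulate inversion-recovery magnetization series under γATP saturation.

    Each observed pool follows A1·[1 − A2·exp(−t/T1obs)] with A1 = its
    steady-state magnetization under saturation and A2 =
    ``config.inversion_efficiency``. Gaussian noise of sd ``ir_noise_sd``
    (falling back to ``noise_sd``) is added to the magnetization values.
    Ground truth is recorded on each series.
    """
    times = np.asarray(list(inversion_times), dtype=float)
    if times.size == 0:
        raise ValidationError("inversion_times: must be nonempty")
    if np.any(times <= 0):
        raise ValidationError("inversion_times: all times must be > 0")
    if np.any(np.diff(np.sort(times)) == 0):
        raise ValidationError("inversion_times: times must be distinct")
    times = np.sort(times)
    if not config.exchange:
        raise ConfigurationError("exchange: inversion recovery needs an ExchangeSpec")
    sd = config.ir_noise_sd if config.ir_noise_sd is not None else config.noise_sd
    rng = np.random.default_rng(config.seed)
    out: dict[str, InversionRecoverySeries] = {}
    a2 = config.inversion_efficiency
    for pool, ex in config.exchange.items():
        a1 = ex.m0 * ex.saturation_factor
        mags = a1 * (1.0 - a2 * np.exp(-times / ex.t1obs))
        if sd > 0:
            mags = mags + rng.normal(scale=sd, size=times.size)
        out[pool] = InversionRecoverySeries(
            pool=pool,
            times=times,
            magnetizations=mags,
            truth={"a1": a1, "a2": a2, "t1obs": ex.t1obs},
        )
    return out


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Two-group expression experiment with planted signal.

    Defaults emulate a scaled-down two-color-free oligonucleotide array
    study on n = 4 vs 4 animals: log2 abundances centered near 9 (linear
    ~500, the conventional target intensity), gene-level spread 1.5, and
    within-group measurement noise 0.25 on the log2 scale. A
    ``planted_fraction`` of genes differ between groups by
    ``planted_log2fc`` log2 units (sign split by ``planted_up_fraction``),
    and ``n_enriched_categories`` functional categories are stacked with
    planted genes.
    """

    n_probesets: int = 1200
    n_genes: int = 1000
    samples_per_group: int = 4
    baseline_log_mean: float = 9.0
    baseline_log_sd: float = 1.5
    noise_log_sd: float = 0.25
    planted_fraction: float = 0.05
    planted_log2fc: float = 2.0
    planted_up_fraction: float = 0.6
    n_categories: int = 25
    category_size: int = 15
    n_enriched_categories: int = 3
    enriched_planted_fraction: float = 0.8
    categories: Mapping[str, Iterable[str]] | None = None  # gene -> category labels
    group_labels: tuple[str, str] = ("C", "TB")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes: must be >= 1")
        if self.n_probesets < self.n_genes:
            raise ValidationError("n_probesets: must be >= n_genes")
        if self.samples_per_group < 2:
            raise ValidationError("samples_per_group: must be >= 2")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ValidationError("planted_fraction: must be in [0, 1]")
        if not 0.0 <= self.planted_up_fraction <= 1.0:
            raise ValidationError("planted_up_fraction: must be in [0, 1]")
        if self.noise_log_sd < 0:
            raise ValidationError("noise_log_sd: must be >= 0")


@dataclass
class ExpressionSimResult:
    """Simulated expression study plus ground truth.

    ``matrix`` is probe sets × samples (linear abundances); ``annotation``
    maps probe sets to genes with a 3′ rank; ``categories`` maps category
    labels to member genes; ``truth`` records the planted genes (with
    direction) and the planted enriched categories.
    """

    matrix: "ExpressionMatrix"
    annotation: pd.DataFrame
    categories: dict[str, list[str]]
    truth: dict


def simulate_expression_dataset(spec: ExpressionSimSpec) -> ExpressionSimResult:
    """Generate a two-group expression matrix with planted signal.

    Deterministic per seed. Probe sets outnumber genes: every gene gets a
    rank-1 (3′-most) probe set; surplus probe sets are duplicates at higher
    ranks with a small probe-specific offset.
    """
    from .enrichment import ExpressionMatrix  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]

    n_planted = int(round(spec.planted_fraction * spec.n_genes))
    planted_idx = rng.choice(spec.n_genes, size=n_planted, replace=False)
    n_up = int(round(spec.planted_up_fraction * n_planted))
    signs = np.zeros(spec.n_genes)
    signs[planted_idx[:n_up]] = 1.0
    signs[planted_idx[n_up:]] = -1.0

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    n = spec.samples_per_group
    group_means = np.stack(
        [np.tile(baseline, (n, 1)).T,
         np.tile(baseline + signs * spec.planted_log2fc, (n, 1)).T],
        axis=1,
    ).reshape(spec.n_genes, 2 * n)
    log2_gene = group_means + rng.normal(0.0, spec.noise_log_sd, group_means.shape)

    # probe sets: one rank-1 probe per gene, surplus probes at ranks 2, 3, ...
    extra_genes = rng.integers(0, spec.n_genes, size=spec.n_probesets - spec.n_genes)
    probe_gene_idx = np.concatenate([np.arange(spec.n_genes), extra_genes])
    ranks = np.ones(spec.n_probesets, dtype=int)
    counters = {g: 1 for g in range(spec.n_genes)}
    for j, g in enumerate(extra_genes, start=spec.n_genes):
        counters[int(g)] += 1
        ranks[j] = counters[int(g)]
    probe_ids = [
        f"ps{i:05d}_{genes[g]}" for i, g in enumerate(probe_gene_idx)
    ]
    probe_offset = rng.normal(0.0, 0.1, spec.n_probesets)
    log2_probe = log2_gene[probe_gene_idx] + probe_offset[:, None]
    values = np.power(2.0, log2_probe)

    sample_ids = [f"{spec.group_labels[0]}{i+1}" for i in range(n)] + [
        f"{spec.group_labels[1]}{i+1}" for i in range(n)
    ]
    group_of = [spec.group_labels[0]] * n + [spec.group_labels[1]] * n
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        groups=pd.Series(group_of, index=sample_ids),
    )
    annotation = pd.DataFrame(
        {
            "probeset_id": probe_ids,
            "gene_id": [genes[g] for g in probe_gene_idx],
            "three_prime_rank": ranks,
        }
    )

    planted_up = [genes[i] for i in np.flatnonzero(signs > 0)]
    planted_down = [genes[i] for i in np.flatnonzero(signs < 0)]
    planted_all = set(planted_up) | set(planted_down)

    if spec.categories is not None:
        categories: dict[str, list[str]] = {}
        for gene, cats in spec.categories.items():
            if gene not in set(genes):
                raise ValidationError(f"categories: unknown gene {gene!r}")
            for c in cats:
                categories.setdefault(c, []).append(gene)
        enriched: list[str] = []
    else:
        categories = {}
        enriched = []
        planted_list = sorted(planted_all)
        null_pool = [g for g in genes if g not in planted_all]
        size = min(spec.category_size, spec.n_genes)
        for c in range(spec.n_categories):
            name = f"CAT{c:03d}"
            if c < spec.n_enriched_categories and planted_list:
                k_planted = min(
                    int(round(spec.enriched_planted_fraction * size)), len(planted_list)
                )
                members = list(
                    rng.choice(planted_list, size=k_planted, replace=False)
                ) + list(rng.choice(null_pool, size=size - k_planted, replace=False))
                enriched.append(name)
            else:
                members = list(rng.choice(genes, size=size, replace=False))
            categories[name] = sorted(set(members))

    truth = {
        "planted_up": sorted(planted_up),
        "planted_down": sorted(planted_down),
        "planted_genes": sorted(planted_all),
        "enriched_categories": enriched,
    }
    return ExpressionSimResult(matrix, annotation, categories, truth)
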
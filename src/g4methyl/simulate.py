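"""Synthetic stand-ins for the instrument data: per-read modification-probability
calls with strand/region-dependent truth and PQS-dependent low-confidence
noise, two-phase BLI sensorgrams, and dose-dependent inhibition curves.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .binding import Sensorgram, bli_forward, ic50_forward, InhibitionCurve
from .pileup import ModProbTriple, ReadModCalls
from .sequence import AmpliconSequence, CpGIndex

__all__ = [
    "TruthConfig",
    "NoiseConfig",
    "PRESET_NAMES",
    "preset_truth",
    "simulate_reads",
    "simulate_sensorgram",
    "simulate_inhibition",
]

PRESET_NAMES = ("control", "dnmt3a", "msssi")

_STRANDS = ("+", "-")
_REGIONS = ("PQS", "non-PQS")


@dataclass(frozen=True)
class TruthConfig:
    """True 5mC probability per (strand, region)."""

    probs: tuple[tuple[str, str, float], ...]  # (strand, region, p)

    def __post_init__(self) -> None:
        seen = {(s, r) for s, r, _ in self.probs}
        if seen != {(s, r) for s in _STRANDS for r in _REGIONS}:
            raise ValueError("truth must cover all 4 strand x region cells")
        for s, r, p in self.probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"truth probability {p} for ({s}, {r}) outside [0,1]")

    def p(self, strand: str, region: str) -> float:
        for s, r, p in self.probs:
            if s == strand and r == region:
                return p
        raise KeyError((strand, region))

    @classmethod
    def from_mapping(cls, m: dict) -> "TruthConfig":
        return cls(
            tuple((s, r, float(m[s][r])) for s in _STRANDS for r in _REGIONS)
        )


@dataclass(frozen=True)
class NoiseConfig:
    high_conf_concentration: float = 30.0
    off_state_concentration: float = 0.5
    low_conf_concentration: float = 5.0
    p_low_conf_inside_pqs: float = 0.30
    p_low_conf_outside: float = 0.02
    false_mod_rate: float = 0.01
    false_5mC_fraction: float = 0.75
    #: sd (probability scale) of per-site truth heterogeneity around the
    #: region mean; offsets are recentred within each strand x region cell so
    #: the cell mean stays exactly the configured truth value. Applied only
    #: where 0 < truth < 1, so an all-unmethylated truth stays clean.
    site_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "high_conf_concentration",
            "off_state_concentration",
            "low_conf_concentration",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in (
            "p_low_conf_inside_pqs",
            "p_low_conf_outside",
            "false_mod_rate",
            "false_5mC_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.site_jitter_sd < 0:
            raise ValueError("site_jitter_sd must be >= 0")


def _load_presets() -> dict:
    import yaml

    ref = resources.files("g4methyl.data") / "presets.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def preset_truth(name: str) -> tuple[TruthConfig, NoiseConfig]:
    """Return the (truth, noise) configuration for a named preset."""
    presets = _load_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    entry = presets[name]
    return TruthConfig.from_mapping(entry["truth"]), NoiseConfig(**entry["noise"])


def simulate_reads(
    amplicon: AmpliconSequence,
    cpg_index: CpGIndex,
    pqs_labels: dict[int, str],
    truth: TruthConfig,
    noise: NoiseConfig,
    n_reads_per_strand: int = 500,
    seed: int = 0,
) -> list[ReadModCalls]:
    """Draw per-read (p_c, p_m, p_h) triples at every CpG site on both strands.

    For each read x site the truth state is Bernoulli in the site's
    (strand, region) methylation probability; the probability triple is then
    drawn from a Dirichlet centred on the truth state, or from a near-uniform
    Dirichlet when the call falls into the region-dependent low-confidence
    component.
    """
    if n_reads_per_strand < 1:
        raise ValueError("n_reads_per_strand must be >= 1")
    positions = list(cpg_index.positions)
    missing = [p for p in positions if p not in pqs_labels]
    if missing:
        raise ValueError(f"pqs_labels missing site position(s) {missing[:5]}")
    rng = np.random.default_rng(seed)
    n_sites = len(positions)
    p_low = np.array(
        [
            noise.p_low_conf_inside_pqs
            if pqs_labels[p] == "PQS"
            else noise.p_low_conf_outside
            for p in positions
        ]
    )
    region_arr = np.array([pqs_labels[p] for p in positions])
    reads: list[ReadModCalls] = []
    for strand in _STRANDS:
        p_truth = np.array([truth.p(strand, pqs_labels[p]) for p in positions])
        if noise.site_jitter_sd > 0:
            jitter = rng.normal(0.0, noise.site_jitter_sd, n_sites)
            for region in _REGIONS:
                mask = (region_arr == region) & (p_truth > 0) & (p_truth < 1)
                if mask.sum() > 1:
                    jitter[mask] -= jitter[mask].mean()  # keep cell mean exact
                p_truth = np.where(
                    mask, np.clip(p_truth + jitter, 1e-3, 1 - 1e-3), p_truth
                )
        shape = (n_reads_per_strand, n_sites)
        # truth states: 0 canonical, 1 5mC, 2 5hmC (5hmC never in truth)
        state = (rng.random(shape) < p_truth).astype(np.int8)
        # unmethylated truths may emit a confident false modified call
        false_mod = (state == 0) & (rng.random(shape) < noise.false_mod_rate)
        false_h = rng.random(shape) >= noise.false_5mC_fraction
        state = np.where(false_mod, np.where(false_h, 2, 1), state)
        low_conf = rng.random(shape) < p_low
        alpha = np.full(shape + (3,), noise.off_state_concentration)
        np.put_along_axis(
            alpha, state[..., None].astype(np.int64), noise.high_conf_concentration, axis=2
        )
        alpha[low_conf] = noise.low_conf_concentration
        draws = rng.gamma(alpha)
        draws /= draws.sum(axis=2, keepdims=True)
        tag = "fwd" if strand == "+" else "rev"
        for i in range(n_reads_per_strand):
            calls = {}
            for j, pos in enumerate(positions):
                p_m = float(draws[i, j, 1])
                p_h = float(draws[i, j, 2])
                calls[pos] = ModProbTriple(max(0.0, 1.0 - p_m - p_h), p_m, p_h)
            reads.append(ReadModCalls(f"{tag}_{i:05d}", strand, calls))
    return reads


def simulate_sensorgram(
    kon: float,
    koff: float,
    rmax: float,
    conc: float = 690e-9,
    t_assoc: float = 300.0,
    t_dissoc: float = 120.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Sensorgram:
    """Two-phase 1:1 sensorgram on a regular grid plus i.i.d. Gaussian noise."""
    if t_assoc <= 0 or t_dissoc <= 0 or dt <= 0:
        raise ValueError("durations and dt must be > 0")
    times = np.arange(dt, t_assoc + t_dissoc + dt / 2, dt)
    clean = bli_forward(times, kon, koff, rmax, conc, t_assoc)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=times.shape)
    return Sensorgram(times, clean, t_assoc, t_assoc + t_dissoc, conc)


def simulate_inhibition(
    f0: float,
    ic50: float,
    hill: float = 1.0,
    concs: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> InhibitionCurve:
    """Dose-response methylation fractions with truncated Gaussian noise."""
    if not (0 < f0 <= 1) or ic50 <= 0 or hill <= 0:
        raise ValueError("need 0 < f0 <= 1, ic50 > 0, hill > 0")
    if concs is None:
        concs = np.concatenate([[0.0], np.geomspace(ic50 / 30, ic50 * 30, 9)])
    concs = np.asarray(concs, float)
    fracs = ic50_forward(concs, f0, ic50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fracs = np.clip(fracs + rng.normal(0.0, noise_sd, size=concs.shape), 0.0, 1.0)
    return InhibitionCurve(concs, fracs)
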
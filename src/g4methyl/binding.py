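"""Forward models and fitting for 1:1 BLI kinetics, IC50 inhibition, and
restriction-protection methylation efficiency.

With a single analyte concentration, kon and koff are identified through the
dissociation tail (koff) and the association observed rate (kobs); Kd =
koff/kon is the headline quantity, and parameter uncertainties are asymptotic
(from the residual covariance), not calibrated error bars.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "Sensorgram",
    "KineticFit",
    "InhibitionCurve",
    "IC50Fit",
    "bli_forward",
    "fit_bli",
    "fit_ic50",
    "methylation_efficiency",
    "read_sensorgram",
    "write_sensorgram",
    "read_inhibition_table",
    "write_inhibition_table",
    "fit_to_json",
]


class FitError(RuntimeError):
    """Raised when a model fit fails to converge or degenerates."""


@dataclass(frozen=True)
class Sensorgram:
    """Two-phase BLI trace: association then dissociation, one analyte conc."""

    times: np.ndarray  # seconds, strictly increasing
    responses: np.ndarray  # instrument response units
    assoc_end: float  # end of association / start of dissociation, s
    dissoc_end: float
    analyte_conc: float  # molar

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        r = np.asarray(self.responses, float)
        if t.shape != r.shape or t.ndim != 1:
            raise ValueError("times and responses must be matching 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.assoc_end < self.dissoc_end):
            raise ValueError("association must precede dissociation")
        if self.analyte_conc <= 0:
            raise ValueError("analyte concentration must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "responses", r)

    @property
    def assoc_mask(self) -> np.ndarray:
        return self.times <= self.assoc_end

    @property
    def dissoc_mask(self) -> np.ndarray:
        return self.times > self.assoc_end


@dataclass(frozen=True)
class KineticFit:
    kon: float  # 1/(M s)
    koff: float  # 1/s
    rmax: float  # response units
    rmse: float
    stderr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kon <= 0 or self.koff <= 0 or self.rmax <= 0:
            raise FitError(
                f"non-positive parameter at optimum: kon={self.kon:.3g}, "
                f"koff={self.koff:.3g}, Rmax={self.rmax:.3g}"
            )

    @property
    def kd(self) -> float:
        return self.koff / self.kon


@dataclass(frozen=True)
class InhibitionCurve:
    inhibitor_concs: np.ndarray  # molar
    methylation_fractions: np.ndarray  # [0, 1]

    def __post_init__(self) -> None:
        c = np.asarray(self.inhibitor_concs, float)
        f = np.asarray(self.methylation_fractions, float)
        if c.shape != f.shape or c.ndim != 1:
            raise ValueError("concs and fractions must be matching 1-D arrays")
        if np.any(c < 0):
            raise ValueError("inhibitor concentrations must be >= 0")
        if np.any((f < 0) | (f > 1)):
            raise ValueError("methylation fractions must lie in [0, 1]")
        if c.size < 4:
            raise ValueError("need at least 4 concentration points")
        object.__setattr__(self, "inhibitor_concs", c)
        object.__setattr__(self, "methylation_fractions", f)


@dataclass(frozen=True)
class IC50Fit:
    ic50: float  # molar
    f0: float  # uninhibited methylation fraction
    hill: float
    rmse: float
    stderr: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise FitError(f"non-positive IC50 at optimum: {self.ic50:.3g}")
        if not (0 < self.f0 <= 1):
            raise FitError(f"f0 {self.f0:.3g} outside (0, 1]")


def bli_forward(
    t: np.ndarray | float,
    kon: float,
    koff: float,
    rmax: float,
    conc: float,
    assoc_end: float,
) -> np.ndarray:
    """1:1 binding response at times t (association up to assoc_end, then decay).

    Association: R(t) = Req (1 - exp(-kobs t)), kobs = kon conc + koff,
    Req = Rmax conc / (conc + koff/kon).  Dissociation continues from the
    response at assoc_end with rate koff, so the trace is continuous.
    """
    if min(kon, koff, rmax, conc) <= 0:
        raise ValueError("kon, koff, Rmax and conc must all be > 0")
    t = np.asarray(t, float)
    kobs = kon * conc + koff
    req = rmax * conc / (conc + koff / kon)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, assoc_end)))
    r_end = req * (1.0 - math.exp(-kobs * assoc_end))
    dissoc = r_end * np.exp(-koff * np.maximum(t - assoc_end, 0.0))
    return np.where(t <= assoc_end, assoc, dissoc)


def _seed_koff(sg: Sensorgram) -> float:
    # log-linear fit of the dissociation tail
    t = sg.times[sg.dissoc_mask] - sg.assoc_end
    r = sg.responses[sg.dissoc_mask]
    keep = r > 1e-12
    if keep.sum() < 2:
        raise FitError("dissociation phase carries no usable signal")
    slope = np.polyfit(t[keep], np.log(r[keep]), 1)[0]
    return max(-slope, 1e-6)


def _seed_kobs(sg: Sensorgram, req_guess: float) -> float:
    # linearize 1 - R/Req on the early association phase
    t = sg.times[sg.assoc_mask]
    r = sg.responses[sg.assoc_mask]
    frac = 1.0 - r / max(req_guess, 1e-12)
    keep = frac > 1e-6
    if keep.sum() < 2:
        raise FitError("association phase carries no usable signal")
    slope = np.polyfit(t[keep], np.log(frac[keep]), 1)[0]
    return max(-slope, 1e-6)


def fit_bli(sg: Sensorgram, kon_seed: float = 1e5) -> KineticFit:
    """Least-squares fit of (kon, koff, Rmax) to a two-phase sensorgram.

    Parameters are optimized in log space (positivity by construction);
    koff is seeded from the dissociation tail and kon from the association
    observed rate, falling back to ``kon_seed`` when that is degenerate.
    """
    if sg.assoc_mask.sum() < 10 or sg.dissoc_mask.sum() < 10:
        raise FitError("need >= 10 points in each phase")
    peak = float(np.max(np.abs(sg.responses)))
    if peak < 1e-9:
        raise FitError("flat sensorgram: no binding signal to fit")
    koff0 = _seed_koff(sg)
    req0 = float(np.max(sg.responses[sg.assoc_mask]))
    kobs0 = _seed_kobs(sg, req0)
    kon0 = (kobs0 - koff0) / sg.analyte_conc
    if kon0 <= 0:
        kon0 = kon_seed
    rmax0 = req0 * (sg.analyte_conc + koff0 / kon0) / sg.analyte_conc

    def residuals(logp: np.ndarray) -> np.ndarray:
        kon, koff, rmax = np.exp(logp)
        model = bli_forward(sg.times, kon, koff, rmax, sg.analyte_conc, sg.assoc_end)
        return model - sg.responses

    x0 = np.log([kon0, koff0, rmax0])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"BLI fit did not converge: {sol.message}")
    kon, koff, rmax = np.exp(sol.x)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    stderr = _asymptotic_stderr(sol, ["kon", "koff", "rmax"], np.exp(sol.x))
    return KineticFit(float(kon), float(koff), float(rmax), rmse, stderr)


def ic50_forward(
    conc: np.ndarray | float, f0: float, ic50: float, hill: float = 1.0
) -> np.ndarray:
    """Log-logistic inhibition with bottom fixed at 0: f0 / (1 + (c/IC50)^h)."""
    conc = np.asarray(conc, float)
    return f0 / (1.0 + (conc / ic50) ** hill)


def fit_ic50(curve: InhibitionCurve, fix_hill: float | None = 1.0) -> IC50Fit:
    """Least-squares fit of (ic50, f0[, hill]); hill fixed at 1 by default."""
    c = curve.inhibitor_concs
    f = curve.methylation_fractions
    if np.ptp(f) < 1e-12:
        raise FitError("all responses equal: IC50 not identifiable")
    f0_0 = max(float(np.max(f)), 1e-3)
    positive = c[c > 0]
    if positive.size == 0:
        raise FitError("need at least one nonzero inhibitor concentration")
    # seed at the concentration nearest half-maximal response
    half_idx = int(np.argmin(np.abs(f - f0_0 / 2.0)))
    ic50_0 = float(c[half_idx]) if c[half_idx] > 0 else float(np.median(positive))

    free_hill = fix_hill is None

    def residuals(p: np.ndarray) -> np.ndarray:
        f0 = p[0]
        ic50 = math.exp(p[1])
        hill = math.exp(p[2]) if free_hill else fix_hill
        return ic50_forward(c, f0, ic50, hill) - f

    x0 = [f0_0, math.log(ic50_0)] + ([0.0] if free_hill else [])
    sol = least_squares(residuals, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise FitError(f"IC50 fit did not converge: {sol.message}")
    f0 = float(sol.x[0])
    ic50 = float(math.exp(sol.x[1]))
    hill = float(math.exp(sol.x[2])) if free_hill else float(fix_hill)
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    names = ["f0", "ic50"] + (["hill"] if free_hill else [])
    scales = np.array([1.0, ic50] + ([hill] if free_hill else []))
    stderr = _asymptotic_stderr(sol, names, scales)
    return IC50Fit(ic50, f0, hill, rmse, stderr)


def _asymptotic_stderr(sol, names: list[str], scales: np.ndarray) -> dict[str, float]:
    """Asymptotic standard errors from J^T J; scales map log-space to natural."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2.0 * sol.cost / dof
        se = np.sqrt(np.diag(cov)) * np.asarray(scales)
        return {k: float(v) for k, v in zip(names, se)}
    except np.linalg.LinAlgError:
        return {k: float("nan") for k in names}


def methylation_efficiency(w0: float, w_meth: float) -> float:
    """Restriction-protection efficiency (w0 - w_meth)/w0.

    w0 is the cleavage extent before methylation, w_meth after.
    """
    if not (0 < w0 <= 1):
        raise ValueError(
            f"w0={w0}: substrate not cleavable" if w0 == 0 else f"w0={w0} outside (0, 1]"
        )
    if not (0 <= w_meth <= 1):
        raise ValueError(f"w_meth={w_meth} outside [0, 1]")
    return (w0 - w_meth) / w0


# --- plain-text IO -----------------------------------------------------------


def read_sensorgram(tsv_path: str | Path, sidecar_path: str | Path) -> Sensorgram:
    """Read a 'time_s\tresponse' TSV plus a YAML sidecar with phase metadata."""
    import yaml

    times, responses = [], []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["time_s", "response"]:
            raise ValueError(f"{tsv_path}: unexpected header {header}")
        for line in fh:
            t_s, r_s = line.rstrip("\n").split("\t")
            times.append(float(t_s))
            responses.append(float(r_s))
    with open(sidecar_path) as fh:
        meta = yaml.safe_load(fh)
    return Sensorgram(
        np.array(times),
        np.array(responses),
        assoc_end=float(meta["assoc_end_s"]),
        dissoc_end=float(meta["dissoc_end_s"]),
        analyte_conc=float(meta["conc_M"]),
    )


def write_sensorgram(
    sg: Sensorgram, tsv_path: str | Path, sidecar_path: str | Path
) -> None:
    import yaml

    with open(tsv_path, "w") as fh:
        fh.write("time_s\tresponse\n")
        for t, r in zip(sg.times, sg.responses):
            fh.write(f"{t:.6g}\t{r:.8g}\n")
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(
            {
                "conc_M": float(sg.analyte_conc),
                "assoc_end_s": float(sg.assoc_end),
                "dissoc_end_s": float(sg.dissoc_end),
            },
            fh,
        )


def read_inhibition_table(path: str | Path) -> InhibitionCurve:
    concs, fracs = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["inhibitor_conc_M", "methylation_fraction"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            c_s, f_s = line.rstrip("\n").split("\t")
            concs.append(float(c_s))
            fracs.append(float(f_s))
    return InhibitionCurve(np.array(concs), np.array(fracs))


def write_inhibition_table(curve: InhibitionCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("inhibitor_conc_M\tmethylation_fraction\n")
        for c, f in zip(curve.inhibitor_concs, curve.methylation_fractions):
            fh.write(f"{c:.6g}\t{f:.8g}\n")


def fit_to_json(fit: KineticFit | IC50Fit, path: str | Path) -> None:
    if isinstance(fit, KineticFit):
        payload = {
            "model": "bli_1to1",
            "kon_per_M_s": fit.kon,
            "koff_per_s": fit.koff,
            "rmax": fit.rmax,
            "kd_M": fit.kd,
            "rmse": fit.rmse,
            "stderr": fit.stderr,
        }
    else:
        payload = {
            "model": "log_logistic_ic50",
            "ic50_M": fit.ic50,
            "f0": fit.f0,
            "hill": fit.hill,
            "rmse": fit.rmse,
            "stderr": fit.stderr,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
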
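"""Dissociation-constant estimation from CSP profiles.

The workflow mirrors standard practice for fast-exchange HSQC titrations:

1. per-residue nonlinear least squares of the single-site depletion isotherm
   (:func:`cspfit.models.single_site_shift`) over (K_D, ddmax);
2. hotspot selection — residues whose shift distance at a chosen point is at
   least the mean plus one sample standard deviation over the candidate set;
3. a site-level K_D from the hotspots, either by fitting the per-point mean
   curve once ("curve-average") or by averaging per-residue K_D's
   ("kd-average");
4. for tandem constructs, a two-site fit: either to the sum of the two site
   means ("summed", the classical XY2 procedure) or jointly to both site
   means with a shared free-ligand concentration ("joint", which preserves
   site identity).

Uncertainties are asymptotic standard errors from the residual-variance-
scaled inverse Gauss-Newton Hessian; a seeded residual bootstrap is available
for small-n honesty.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .csp import CSPProfile, ExchangeCall
from .models import SingleSiteParams, TwoSiteParams, solve_two_site_free_ligand
from .peaks import TitrationSeries

__all__ = [
    "SingleSiteFit",
    "HotspotSelection",
    "TwoSiteFit",
    "InsufficientDataError",
    "NonBindingError",
    "fit_single_residue",
    "select_hotspots",
    "site_mean_curve",
    "fit_site_average",
    "fit_two_site",
    "report",
    "format_report",
]

KD_BOUNDS = (1e-6, 1e3)   # mM
DD_BOUNDS = (0.0, 10.0)   # ppm
_TOL = 1e-12


class InsufficientDataError(ValueError):
    """Too few observed titration points (or residues) to fit."""


class NonBindingError(ValueError):
    """Profile shows no perturbation above the floor; nothing to fit."""


@dataclass(frozen=True)
class SingleSiteFit:
    residue_ids: tuple[int, ...]
    kd: float          # mM
    kd_sd: float       # mM
    ddmax: float       # ppm
    ddmax_sd: float    # ppm
    n_points: int
    converged: bool
    residual_rms: float  # ppm
    mode: str = "single"


@dataclass(frozen=True)
class HotspotSelection:
    site_label: str
    selected: tuple[int, ...]
    threshold: float  # ppm, == mean + sd
    mean: float
    sd: float
    point_used: int
    intermediate: tuple[int, ...] = ()  # excluded from the statistics


@dataclass(frozen=True)
class TwoSiteFit:
    k1: float
    k1_sd: float
    k2: float
    k2_sd: float
    d1: float
    d2: float
    converged: bool
    residual_rms: float
    site1_label: str = "site1"
    site2_label: str = "site2"
    mode: str = "joint"
    messages: tuple[str, ...] = ()


def _single_model(x: np.ndarray, a: np.ndarray, kd: float, ddmax: float) -> np.ndarray:
    b_ = 1.0 + kd / a
    s = b_ + x
    return 0.5 * ddmax * (s - np.sqrt(np.maximum(s * s - 4.0 * x, 0.0)))


def _initial_guess(x: np.ndarray, y: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """ddmax0 = 1.2 * max(y); kd0 = ligand concentration at half the maximal
    observed shift, linearly interpolated along the curve."""
    ymax = float(y.max())
    dd0 = min(max(1.2 * ymax, DD_BOUNDS[0] + 1e-6), DD_BOUNDS[1])
    lig = x * a
    half = 0.5 * ymax
    idx = int(np.argmax(y >= half))
    if idx == 0:
        kd0 = max(lig[1] / 2.0, KD_BOUNDS[0]) if len(lig) > 1 else 1.0
    else:
        y0, y1 = y[idx - 1], y[idx]
        frac = 0.0 if y1 == y0 else (half - y0) / (y1 - y0)
        kd0 = lig[idx - 1] + frac * (lig[idx] - lig[idx - 1])
    kd0 = float(np.clip(kd0, KD_BOUNDS[0] * 10, KD_BOUNDS[1] / 10))
    return kd0, dd0


def _covariance_sds(res, n: int, p: int) -> np.ndarray:
    """Asymptotic SEs: sqrt(diag(s^2 (J'J)^-1)), s^2 = SSR/(n-p).
    Singular information (non-identifiable parameter) yields inf."""
    dof = n - p
    if dof <= 0:
        return np.full(p, np.inf)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        d = np.diag(cov)
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise np.linalg.LinAlgError
        return np.sqrt(d)
    except np.linalg.LinAlgError:
        # pseudo-inverse for the identifiable directions, inf elsewhere
        u, sv, _ = np.linalg.svd(jtj)
        tol = sv.max() * max(jtj.shape) * np.finfo(float).eps if sv.size else 0.0
        sds = np.empty(p)
        for i in range(p):
            contrib = sum((u[i, k] ** 2) / sv[k] for k in range(len(sv)) if sv[k] > tol)
            dead = any(sv[k] <= tol and abs(u[i, k]) > 1e-8 for k in range(len(sv)))
            sds[i] = np.inf if dead else np.sqrt(s2 * contrib)
        return sds


def _fit_single_curve(x: np.ndarray, y: np.ndarray, a: np.ndarray,
                      residue_ids: tuple[int, ...], mode: str) -> SingleSiteFit:
    kd0, dd0 = _initial_guess(x, y, a)

    def resid(theta):
        return _single_model(x, a, theta[0], theta[1]) - y

    res = least_squares(resid, x0=[kd0, dd0],
                        bounds=([KD_BOUNDS[0], DD_BOUNDS[0]],
                                [KD_BOUNDS[1], DD_BOUNDS[1]]),
                        method="trf", ftol=_TOL, xtol=_TOL, gtol=_TOL)
    sds = _covariance_sds(res, len(y), 2)
    return SingleSiteFit(
        residue_ids=residue_ids,
        kd=float(res.x[0]), kd_sd=float(sds[0]),
        ddmax=float(res.x[1]), ddmax_sd=float(sds[1]),
        n_points=len(y), converged=bool(res.success),
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))), mode=mode)


def fit_single_residue(profile: CSPProfile, series: TitrationSeries,
                       epsilon: float = 0.005) -> SingleSiteFit:
    """Single-site fit of one residue's CSP trajectory.

    Missing points are excluded, never imputed; needs >= 4 observed points
    including the free reference and at least one shift above ``epsilon``.
    """
    obs = profile.observed
    if not obs[0]:
        raise InsufficientDataError(
            f"residue {profile.residue_id}: free reference point missing")
    if obs.sum() < 4:
        raise InsufficientDataError(
            f"residue {profile.residue_id}: {int(obs.sum())} observed points, need >= 4")
    y = profile.delta_delta[obs]
    if np.all(y < epsilon):
        raise NonBindingError(
            f"residue {profile.residue_id}: all shift distances below {epsilon:g} ppm")
    x = series.ratios[obs]
    a = series.protein_concs[obs]
    return _fit_single_curve(x, y, a, (profile.residue_id,), mode="single")


def select_hotspots(profiles, point: int | None = None,
                    residue_range=None, exchange_calls=None,
                    site_label: str = "") -> HotspotSelection:
    """Mean-plus-one-SD hotspot rule.

    Over the candidate residues (optionally restricted to ``residue_range``,
    an inclusive ``(lo, hi)`` pair or explicit id collection), compute the
    mean and sample standard deviation (n-1 denominator) of the weighted
    shift distance at titration point ``point`` (default: the final point,
    which maximises dynamic range) and keep residues at or above mean + SD.
    Intermediate-exchange residues (per ``exchange_calls``) are excluded from
    the statistics and reported separately.
    """
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no profiles given")
    npoints = len(profiles[0].delta_delta)
    if point is None:
        point = npoints - 1
    if point < 0:
        point += npoints

    if residue_range is None:
        allowed = None
    elif isinstance(residue_range, tuple) and len(residue_range) == 2:
        lo, hi = residue_range
        allowed = set(range(int(lo), int(hi) + 1))
    else:
        allowed = {int(r) for r in residue_range}

    intermediate = set()
    if exchange_calls is not None:
        intermediate = {c.residue_id for c in exchange_calls
                        if c.regime == "intermediate"}

    values: dict[int, float] = {}
    excluded: list[int] = []
    for prof in profiles:
        if allowed is not None and prof.residue_id not in allowed:
            continue
        if prof.residue_id in intermediate:
            excluded.append(prof.residue_id)
            continue
        if prof.flags[point] != "observed":
            excluded.append(prof.residue_id)
            continue
        values[prof.residue_id] = float(prof.delta_delta[point])

    if len(values) < 3:
        raise InsufficientDataError(
            f"only {len(values)} usable residues at point {point}, need >= 3")
    arr = np.array([values[r] for r in sorted(values)])
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    threshold = mean + sd
    # eps-scale slack so an all-equal (sd ~ 0) set selects every residue
    # despite rounding in the mean
    tol = 8.0 * np.finfo(float).eps * max(1.0, abs(threshold))
    selected = tuple(r for r in sorted(values) if values[r] >= threshold - tol)
    return HotspotSelection(site_label=site_label, selected=selected,
                            threshold=threshold, mean=mean, sd=sd,
                            point_used=point,
                            intermediate=tuple(sorted(set(excluded))))


def site_mean_curve(selection: HotspotSelection, profiles) -> np.ndarray:
    """Per-point mean shift distance over the selected residues."""
    by_id = {p.residue_id: p for p in profiles}
    missing = [r for r in selection.selected if r not in by_id]
    if missing:
        raise KeyError(f"selected residues missing from profiles: {missing}")
    stack = np.vstack([by_id[r].delta_delta for r in selection.selected])
    if np.isnan(stack).any():
        raise InsufficientDataError(
            "selected residues have missing points; exclude intermediate-"
            "exchange residues before averaging")
    return stack.mean(axis=0)


def fit_site_average(selection: HotspotSelection, profiles,
                     series: TitrationSeries,
                     mode: str = "curve-average") -> SingleSiteFit:
    """Site-level single-site fit from the hotspot residues.

    ``curve-average`` (default) fits the per-point mean curve once;
    ``kd-average`` fits each residue separately and averages the K_D's, with
    the SD across residues as the uncertainty.  The two agree when the
    hotspots share one true K_D and diverge otherwise.
    """
    if not selection.selected:
        raise InsufficientDataError("empty hotspot selection")
    if mode == "curve-average":
        y = site_mean_curve(selection, profiles)
        return _fit_single_curve(series.ratios, y, series.protein_concs,
                                 tuple(selection.selected), mode=mode)
    if mode == "kd-average":
        by_id = {p.residue_id: p for p in profiles}
        fits = [fit_single_residue(by_id[r], series) for r in selection.selected]
        kds = np.array([f.kd for f in fits])
        dds = np.array([f.ddmax for f in fits])
        kd_sd = float(kds.std(ddof=1)) if len(kds) > 1 else float(fits[0].kd_sd)
        dd_sd = float(dds.std(ddof=1)) if len(dds) > 1 else float(fits[0].ddmax_sd)
        return SingleSiteFit(
            residue_ids=tuple(selection.selected),
            kd=float(kds.mean()), kd_sd=kd_sd,
            ddmax=float(dds.mean()), ddmax_sd=dd_sd,
            n_points=fits[0].n_points,
            converged=all(f.converged for f in fits),
            residual_rms=float(np.sqrt(np.mean([f.residual_rms ** 2 for f in fits]))),
            mode=mode)
    raise ValueError(f"unknown mode {mode!r}")


def _start_from_single(x, y, a) -> tuple[float, float]:
    try:
        f = _fit_single_curve(x, y, np.full_like(x, a), (), mode="start")
        return f.kd, f.ddmax
    except Exception:
        return float(a), float(1.2 * y.max())


def fit_two_site(site1_mean: np.ndarray, site2_mean: np.ndarray,
                 series: TitrationSeries, mode: str = "summed",
                 site1_label: str = "site1",
                 site2_label: str = "site2") -> TwoSiteFit:
    """Two-site (tandem construct) fit on the two site-mean CSP curves.

    ``summed`` fits the XY2 curve to the per-point sum of the site means —
    the classical procedure — and afterwards assigns delta_1 to the site
    whose mean saturates higher (a heuristic: the summed curve alone cannot
    identify which K goes with which site).  ``joint`` fits both site means
    simultaneously with a shared free-ligand concentration and preserves
    site identity by construction.
    """
    y1 = np.asarray(site1_mean, dtype=float)
    y2 = np.asarray(site2_mean, dtype=float)
    if y1.shape != y2.shape or len(y1) != len(series.points):
        raise ValueError("site means must align with the titration points")
    if np.isnan(y1).any() or np.isnan(y2).any():
        raise InsufficientDataError("site-mean curves contain missing points")
    if len(y1) < 6:
        raise InsufficientDataError(f"{len(y1)} points, need >= 6 for a two-site fit")
    lt = series.ligand_concs
    x = series.ratios
    p = float(series.points[0].protein_conc)

    k10, d10 = _start_from_single(x, y1, p)
    k20, d20 = _start_from_single(x, y2, p)
    x0 = [np.clip(k10, *KD_BOUNDS), np.clip(k20, *KD_BOUNDS),
          np.clip(d10, *DD_BOUNDS), np.clip(d20, *DD_BOUNDS)]
    lo = [KD_BOUNDS[0]] * 2 + [DD_BOUNDS[0]] * 2
    hi = [KD_BOUNDS[1]] * 2 + [DD_BOUNDS[1]] * 2

    def free_ligand(k1, k2):
        return solve_two_site_free_ligand(
            lt, TwoSiteParams(k1=k1, k2=k2, d1=1.0, d2=1.0, p=p))

    messages: list[str] = []
    if mode == "summed":
        ysum = y1 + y2

        def resid(theta):
            k1, k2, d1, d2 = theta
            L = free_ligand(k1, k2)
            return d1 * L / (k1 + L) + d2 * L / (k2 + L) - ysum

        res = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf",
                            ftol=_TOL, xtol=_TOL, gtol=_TOL)
        # label by amplitude: d1 -> site whose mean saturates higher
        lab1, lab2 = site1_label, site2_label
        hi_site = site1_label if y1.max() >= y2.max() else site2_label
        lo_site = site2_label if hi_site == site1_label else site1_label
        d_hi = site1_label if res.x[2] >= res.x[3] else site2_label
        if d_hi != hi_site:
            # swap so the larger amplitude carries the higher-saturating label
            res.x = res.x[[1, 0, 3, 2]]
            res.jac = res.jac[:, [1, 0, 3, 2]]
        lab1, lab2 = hi_site, lo_site
        warnings.warn(
            "summed two-site fit: site labels assigned by the amplitude "
            "heuristic (larger fitted delta -> higher-saturating site mean); "
            "use mode='joint' to preserve site identity", stacklevel=2)
        messages.append("labels assigned by amplitude heuristic")
        n = len(ysum)
    elif mode == "joint":
        def resid(theta):
            k1, k2, d1, d2 = theta
            L = free_ligand(k1, k2)
            return np.concatenate([d1 * L / (k1 + L) - y1,
                                   d2 * L / (k2 + L) - y2])

        res = least_squares(resid, x0=x0, bounds=(lo, hi), method="trf",
                            ftol=_TOL, xtol=_TOL, gtol=_TOL)
        lab1, lab2 = site1_label, site2_label
        n = 2 * len(y1)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    sds = _covariance_sds(res, n, 4)
    # A site with ~zero amplitude contributes no curve of its own; its K
    # would be determined only through the ligand-depletion coupling, which
    # is not a defensible basis for a binding constant.  Report it as
    # unidentifiable.
    for i, d in enumerate(res.x[2:4]):
        if d < 1e-6:
            sds[i] = np.inf
    if not np.all(np.isfinite(sds)):
        messages.append("non-identifiable parameter(s): unbounded uncertainty")
    return TwoSiteFit(
        k1=float(res.x[0]), k1_sd=float(sds[0]),
        k2=float(res.x[1]), k2_sd=float(sds[1]),
        d1=float(res.x[2]), d2=float(res.x[3]),
        converged=bool(res.success),
        residual_rms=float(np.sqrt(np.mean(res.fun ** 2))),
        site1_label=lab1, site2_label=lab2, mode=mode,
        messages=tuple(messages))


def bootstrap_kd_sd(profile: CSPProfile, series: TitrationSeries,
                    n_boot: int = 200, seed: int = 0) -> float:
    """Residual-bootstrap SD of the single-residue K_D (seeded)."""
    base = fit_single_residue(profile, series)
    obs = profile.observed
    x, a = series.ratios[obs], series.protein_concs[obs]
    y = profile.delta_delta[obs]
    resid = y - _single_model(x, a, base.kd, base.ddmax)
    rng = np.random.default_rng(seed)
    kds = []
    for _ in range(n_boot):
        yb = _single_model(x, a, base.kd, base.ddmax) + rng.choice(resid, size=len(resid))
        try:
            kds.append(_fit_single_curve(x, np.maximum(yb, 0.0), a, (), "boot").kd)
        except Exception:
            continue
    return float(np.std(kds, ddof=1)) if len(kds) > 1 else float("nan")


# ---------------------------------------------------------------------------
# reporting

def _kd_str(kd_mm: float, sd_mm: float) -> str:
    if kd_mm < 1.0:
        return f"{kd_mm * 1e3:.4g} ± {sd_mm * 1e3:.3g} µM"
    return f"{kd_mm:.4g} ± {sd_mm:.3g} mM"


def report(fits=(), selections=(), calls=(), meta=None) -> dict:
    """Assemble a JSON-serialisable report of fits, hotspot selections and
    exchange calls; K_D values are carried in both mM and uM."""
    out: dict = {"meta": dict(meta or {})}
    out["fits"] = []
    for f in fits:
        if isinstance(f, SingleSiteFit):
            out["fits"].append({
                "model": "single-site", "mode": f.mode,
                "residues": list(f.residue_ids),
                "kd_mM": f.kd, "kd_sd_mM": f.kd_sd,
                "kd_uM": f.kd * 1e3, "kd_sd_uM": f.kd_sd * 1e3,
                "ddmax_ppm": f.ddmax, "ddmax_sd_ppm": f.ddmax_sd,
                "n_points": f.n_points, "converged": f.converged,
                "residual_rms_ppm": f.residual_rms,
            })
        else:
            out["fits"].append({
                "model": "two-site", "mode": f.mode,
                "site1": f.site1_label, "site2": f.site2_label,
                "k1_mM": f.k1, "k1_sd_mM": f.k1_sd,
                "k1_uM": f.k1 * 1e3, "k1_sd_uM": f.k1_sd * 1e3,
                "k2_mM": f.k2, "k2_sd_mM": f.k2_sd,
                "k2_uM": f.k2 * 1e3, "k2_sd_uM": f.k2_sd * 1e3,
                "d1_ppm": f.d1, "d2_ppm": f.d2,
                "converged": f.converged,
                "residual_rms_ppm": f.residual_rms,
                "messages": list(f.messages),
            })
    if selections:
        out["hotspots"] = [{
            "site": s.site_label, "selected": list(s.selected),
            "threshold_ppm": s.threshold, "mean_ppm": s.mean, "sd_ppm": s.sd,
            "point_used": s.point_used,
            "excluded_intermediate": list(s.intermediate),
        } for s in selections]
    if calls:
        out["exchange_calls"] = [{
            "residue_id": c.residue_id, "regime": c.regime, "evidence": c.evidence,
        } for c in calls]
    return out


def format_report(rep: dict) -> str:
    """Human-readable rendering of :func:`report` output."""
    lines = ["CSP titration fit report", "=" * 25]
    for k, v in rep.get("meta", {}).items():
        lines.append(f"{k}: {v}")
    for f in rep.get("fits", []):
        lines.append("")
        conv = "" if f["converged"] else "   [NOT CONVERGED]"
        if f["model"] == "single-site":
            lines.append(f"Single-site fit ({f['mode']}), residues "
                         f"{f['residues']}{conv}")
            lines.append("  K_D = " + _kd_str(f["kd_mM"], f["kd_sd_mM"]))
            lines.append(f"  ddmax = {f['ddmax_ppm']:.4g} ± "
                         f"{f['ddmax_sd_ppm']:.3g} ppm")
        else:
            lines.append(f"Two-site fit ({f['mode']}){conv}")
            lines.append(f"  {f['site1']}: K_D = " + _kd_str(f["k1_mM"], f["k1_sd_mM"])
                         + f", delta = {f['d1_ppm']:.4g} ppm")
            lines.append(f"  {f['site2']}: K_D = " + _kd_str(f["k2_mM"], f["k2_sd_mM"])
                         + f", delta = {f['d2_ppm']:.4g} ppm")
            for msg in f.get("messages", []):
                lines.append(f"  note: {msg}")
        lines.append(f"  residual RMS = {f['residual_rms_ppm']:.3g} ppm, "
                     f"n = {f.get('n_points', '')}")
    for s in rep.get("hotspots", []):
        lines.append("")
        lines.append(f"Hotspots {s['site']}: {s['selected']} "
                     f"(threshold {s['threshold_ppm']:.4g} ppm = "
                     f"mean {s['mean_ppm']:.4g} + SD {s['sd_ppm']:.4g}, "
                     f"point {s['point_used']})")
        if s["excluded_intermediate"]:
            lines.append(f"  excluded (intermediate/missing): "
                         f"{s['excluded_intermediate']}")
    if rep.get("exchange_calls"):
        lines.append("")
        lines.append("Exchange regimes:")
        for c in rep["exchange_calls"]:
            lines.append(f"  {c['residue_id']:>4d}  {c['regime']:<12s} {c['evidence']}")
    return "\n".join(lines) + "\n"
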
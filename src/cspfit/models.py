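"""Equilibrium binding models for fast-exchange NMR titrations.

Two forward models map total ligand to the observed population-weighted
chemical-shift change of a receptor resonance:

* a single-site 1:1 model with explicit ligand depletion (the receptor
  concentration is comparable to K_D, so free ligand != total ligand); the
  bound fraction is the physical root of a quadratic in the complex
  concentration, and the observed shift change is ``ddmax * fraction_bound``;

* a two-independent-site model for a tandem-domain construct binding two
  ligands (2:1 ligand:receptor stoichiometry).  Free ligand L is the root of

      L + p*L/(K1 + L) + p*L/(K2 + L) = l_tot

  on [0, l_tot], a cubic in L solved in closed form by the trigonometric
  method and polished by Newton steps; the observed shift change is the sum
  of per-site occupancies scaled by the per-site saturation shifts.

Every closed form has an independent bisection oracle next to it so the
algebra can be verified numerically rather than trusted.

Concentrations are in mM throughout; shifts in ppm.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SingleSiteParams",
    "TwoSiteParams",
    "single_site_shift",
    "single_site_oracle",
    "solve_two_site_free_ligand",
    "two_site_free_ligand_bisect",
    "two_site_shift",
    "two_site_site_shifts",
]


@dataclass(frozen=True)
class SingleSiteParams:
    """1:1 binding parameters: K_D ``kd`` (mM), saturation shift ``ddmax``
    (ppm) and total receptor concentration ``a`` (mM)."""

    kd: float
    ddmax: float
    a: float

    def __post_init__(self) -> None:
        if self.kd < 0:
            raise ValueError(f"kd must be >= 0, got {self.kd}")
        if self.ddmax < 0:
            raise ValueError(f"ddmax must be >= 0, got {self.ddmax}")
        if self.a <= 0:
            raise ValueError(f"protein concentration a must be > 0, got {self.a}")


@dataclass(frozen=True)
class TwoSiteParams:
    """Two-independent-site parameters for a tandem construct.

    ``k1``/``k2`` are the per-site dissociation constants (mM), ``d1``/``d2``
    the per-site saturation shift changes (ppm), ``p`` the total protein
    concentration (mM).  Each protein carries one copy of each site.
    """

    k1: float
    k2: float
    d1: float
    d2: float
    p: float

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("site dissociation constants must be > 0")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("saturation shifts must be >= 0")
        if self.p <= 0:
            raise ValueError("protein concentration must be > 0")


def single_site_shift(x, params: SingleSiteParams):
    """Observed shift change at molar ratio ``x = b/a`` under 1:1 binding.

    y = (ddmax/2) * (B + x - sqrt((B + x)^2 - 4x)),  B = 1 + kd/a,

    which equals ddmax times the bound fraction of the receptor with ligand
    depletion accounted for.  Accepts scalar or array ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("molar ratio x must be >= 0")
    b_ = 1.0 + params.kd / params.a
    s = b_ + x
    disc = s * s - 4.0 * x
    # disc >= (B - x)^2 >= 0 analytically; clip float dust near the
    # stoichiometric point (kd = 0, x = 1).
    disc = np.maximum(disc, 0.0)
    y = 0.5 * params.ddmax * (s - np.sqrt(disc))
    return float(y) if y.ndim == 0 else y


def single_site_oracle(x, params: SingleSiteParams):
    """Independent check of :func:`single_site_shift`.

    Solves the 1:1 mass balance  [PL]^2 - (a + b + kd)[PL] + a*b = 0  for the
    physical root by bracketed root finding on [0, min(a, b)] and returns
    ``ddmax * [PL]/a``.  Shares no algebra with the closed form.
    """
    xs = np.atleast_1d(np.asarray(x, dtype=float))
    a, kd, ddmax = params.a, params.kd, params.ddmax
    out = np.empty_like(xs)
    for i, xi in enumerate(xs):
        b = xi * a
        if b == 0.0:
            out[i] = 0.0
            continue
        hi = min(a, b)

        def f(c, _b=b):
            return c * c - (a + _b + kd) * c + a * _b

        if f(hi) >= 0.0:  # kd == 0: root sits at the bracket end
            pl = hi
        else:
            pl = brentq(f, 0.0, hi, xtol=1e-30, rtol=8.9e-16)
        out[i] = ddmax * pl / a
    return float(out[0]) if np.ndim(x) == 0 else out


def _mass_balance(L: float, lt: float, p: float, k1: float, k2: float) -> float:
    return L + p * L / (k1 + L) + p * L / (k2 + L) - lt


def _solve_one(lt: float, p: float, k1: float, k2: float) -> float:
    if lt <= 0.0:
        return 0.0
    # Cubic in L from clearing denominators of the mass balance:
    #   L^3 + c2 L^2 + c1 L + c0 = 0
    c2 = k1 + k2 + 2.0 * p - lt
    c1 = k1 * k2 + (p - lt) * (k1 + k2)
    c0 = -lt * k1 * k2
    q = (3.0 * c1 - c2 * c2) / 9.0
    r = (9.0 * c2 * c1 - 27.0 * c0 - 2.0 * c2 ** 3) / 54.0

    L = None
    if q < 0.0:
        w = r / math.sqrt(-(q ** 3))
        if abs(w) <= 1.0 + 1e-12:
            w = min(1.0, max(-1.0, w))
            theta = math.acos(w)
            m = 2.0 * math.sqrt(-q)
            roots = [m * math.cos((theta + 2.0 * math.pi * k) / 3.0) - c2 / 3.0
                     for k in range(3)]
            tol = 1e-9 * max(1.0, lt)
            cands = [x for x in roots if -tol <= x <= lt + tol]
            if cands:
                L = min(cands, key=lambda x: abs(_mass_balance(x, lt, p, k1, k2)))
    if L is None:
        # Degenerate or ill-conditioned cubic: the physical root is always
        # bracketed by [0, lt] since the mass balance is monotone in L.
        warnings.warn(
            "two-site cubic ill-conditioned; falling back to bisection",
            RuntimeWarning,
            stacklevel=3,
        )
        L = brentq(_mass_balance, 0.0, lt, args=(lt, p, k1, k2),
                   xtol=1e-30, rtol=8.9e-16)
    # Newton polish on the (strictly increasing, well-conditioned) mass
    # balance removes the cancellation error of the trig closed form.
    for _ in range(3):
        g = _mass_balance(L, lt, p, k1, k2)
        gp = 1.0 + p * k1 / (k1 + L) ** 2 + p * k2 / (k2 + L) ** 2
        L -= g / gp
        if L < 0.0:
            L = 0.0
        elif L > lt:
            L = lt
    return L


def solve_two_site_free_ligand(l_tot, params: TwoSiteParams):
    """Free-ligand concentration L (mM) at total ligand ``l_tot`` for two
    independent sites on one receptor.

    Closed-form trigonometric solution of the mass-balance cubic, Newton
    polished; the root is unique on [0, l_tot].  Accepts scalar or array.
    """
    lts = np.atleast_1d(np.asarray(l_tot, dtype=float))
    if np.any(lts < 0):
        raise ValueError("total ligand must be >= 0")
    out = np.array([_solve_one(lt, params.p, params.k1, params.k2) for lt in lts])
    return float(out[0]) if np.ndim(l_tot) == 0 else out


def two_site_free_ligand_bisect(l_tot, params: TwoSiteParams):
    """Bisection oracle for :func:`solve_two_site_free_ligand` (no shared
    algebra: roots the mass balance directly on [0, l_tot])."""
    lts = np.atleast_1d(np.asarray(l_tot, dtype=float))
    out = np.empty_like(lts)
    for i, lt in enumerate(lts):
        if lt <= 0.0:
            out[i] = 0.0
        else:
            out[i] = brentq(_mass_balance, 0.0, lt,
                            args=(lt, params.p, params.k1, params.k2),
                            xtol=1e-30, rtol=8.9e-16)
    return float(out[0]) if np.ndim(l_tot) == 0 else out


def two_site_site_shifts(l_tot, params: TwoSiteParams):
    """Per-site shift contributions ``(y1, y2)`` with
    ``yi = di * L/(Ki + L)``; their sum is :func:`two_site_shift`."""
    L = solve_two_site_free_ligand(l_tot, params)
    y1 = params.d1 * L / (params.k1 + L)
    y2 = params.d2 * L / (params.k2 + L)
    return y1, y2


def two_site_shift(l_tot, params: TwoSiteParams):
    """Summed two-site fast-exchange curve: the quantity fit to the sum of
    the two site-mean CSP curves of a tandem construct."""
    y1, y2 = two_site_site_shifts(l_tot, params)
    return y1 + y2
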
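"""Node-age calibration densities for molecular-clock dating designs.

Two families are provided, both normalized densities on node age in Myr
before present:

``uniform_soft``
    Mass ``1 - p_L - p_U`` spread uniformly over ``[t_L, t_U]`` with
    continuous exponential tails holding mass ``p_L`` below the minimum and
    ``p_U`` above the maximum.  A *hard* bound is expressed as tail mass
    1e-300 rather than exactly 0, which keeps every density strictly
    positive and avoids log-underflow in downstream samplers.

``cauchy_lower``
    A minimum-age calibration: mass ``1 - p_L`` follows a Cauchy with
    location ``t_L (1 + p)`` and scale ``c t_L`` truncated to ``t > t_L``
    (offset fraction ``p``, scale fraction ``c``), plus an exponential
    lower tail of mass ``p_L`` below the minimum.  The heavy right tail
    encodes that a sparse fossil record says little about how much older
    than its oldest fossil a clade may be.

Only the masses and bound placements are contracts; the *shape* of the
soft tails is a configurable implementation detail (exponential here,
matched for density continuity at the bound), since different dating
programs use different tail dialects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Union

import numpy as np
import scipy.integrate
import scipy.stats
import yaml

__all__ = [
    "CalibrationDensity",
    "make_calibration",
    "tail_mass",
    "sample",
    "load_calibrations",
    "calibration_report",
    "HARD",
]

HARD = 1e-300  # tail mass used to express a hard bound without exact zeros


@dataclass(frozen=True)
class CalibrationDensity:
    """A normalized node-age prior density (ages in Myr before present)."""

    kind: str  # "uniform_soft" | "cauchy_lower"
    t_L: float
    t_U: Optional[float] = None
    p_L: float = HARD
    p_U: Optional[float] = None
    p: Optional[float] = None  # Cauchy offset fraction
    c: Optional[float] = None  # Cauchy scale fraction

    # -- derived quantities ------------------------------------------------

    def _uniform_parts(self):
        h = (1.0 - self.p_L - (self.p_U or 0.0)) / (self.t_U - self.t_L)
        lam_lo = h / self.p_L if self.p_L > 0 else np.inf
        lam_hi = h / self.p_U if (self.p_U or 0) > 0 else np.inf
        return h, lam_lo, lam_hi

    def _cauchy(self):
        loc = self.t_L * (1.0 + self.p)
        scale = self.c * self.t_L
        base = scipy.stats.cauchy(loc=loc, scale=scale)
        upper_mass = base.sf(self.t_L)  # untruncated mass above t_L
        f0 = (1.0 - self.p_L) * base.pdf(self.t_L) / upper_mass
        lam = f0 / self.p_L if self.p_L > 0 else np.inf
        return base, upper_mass, f0, lam

    # -- density / distribution -------------------------------------------

    def pdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.kind == "uniform_soft":
            h, lam_lo, lam_hi = self._uniform_parts()
            below, above = t < self.t_L, t > self.t_U
            mid = ~below & ~above
            out[mid] = h
            if self.p_L > 0:
                with np.errstate(over="ignore", under="ignore"):
                    out[below] = h * np.exp(lam_lo * (t[below] - self.t_L))
            if (self.p_U or 0) > 0:
                with np.errstate(over="ignore", under="ignore"):
                    out[above] = h * np.exp(-lam_hi * (t[above] - self.t_U))
        else:
            base, upper_mass, f0, lam = self._cauchy()
            below = t <= self.t_L
            out[~below] = (1.0 - self.p_L) * base.pdf(t[~below]) / upper_mass
            if self.p_L > 0:
                with np.errstate(over="ignore", under="ignore"):
                    out[below] = f0 * np.exp(lam * (t[below] - self.t_L))
        return out

    def cdf(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if self.kind == "uniform_soft":
            h, lam_lo, lam_hi = self._uniform_parts()
            below, above = t < self.t_L, t > self.t_U
            mid = ~below & ~above
            with np.errstate(over="ignore", under="ignore"):
                out[below] = self.p_L * np.exp(lam_lo * (t[below] - self.t_L))
            out[mid] = self.p_L + h * (t[mid] - self.t_L)
            with np.errstate(over="ignore", under="ignore"):
                out[above] = 1.0 - (self.p_U or 0.0) * np.exp(
                    -lam_hi * (t[above] - self.t_U)
                )
        else:
            base, upper_mass, f0, lam = self._cauchy()
            below = t <= self.t_L
            with np.errstate(over="ignore", under="ignore"):
                out[below] = self.p_L * np.exp(lam * (t[below] - self.t_L))
            out[~below] = self.p_L + (1.0 - self.p_L) * (
                base.cdf(t[~below]) - base.cdf(self.t_L)
            ) / upper_mass
        return out

    def ppf(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0) | (u >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        out = np.empty_like(u)
        if self.kind == "uniform_soft":
            h, lam_lo, lam_hi = self._uniform_parts()
            lo, hi = u < self.p_L, u > 1.0 - (self.p_U or 0.0)
            mid = ~lo & ~hi
            out[lo] = self.t_L + np.log(u[lo] / self.p_L) / lam_lo
            out[mid] = self.t_L + (u[mid] - self.p_L) / h
            out[hi] = self.t_U - np.log((1.0 - u[hi]) / self.p_U) / lam_hi
        else:
            base, upper_mass, f0, lam = self._cauchy()
            lo = u < self.p_L
            out[lo] = self.t_L + np.log(u[lo] / self.p_L) / lam
            q = base.cdf(self.t_L) + (u[~lo] - self.p_L) / (1.0 - self.p_L) * upper_mass
            out[~lo] = base.ppf(q)
        return out

    # -- sampling ----------------------------------------------------------

    def sample(self, n: int, seed: int) -> np.ndarray:
        """``n`` i.i.d. draws by inverse-CDF sampling (deterministic per seed)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        u = rng.uniform(np.finfo(float).tiny, 1.0 - 1e-12, size=n)
        return self.ppf(u)

    # -- integral checks ---------------------------------------------------

    def integral(self) -> float:
        """Total mass by adaptive quadrature (should be 1 within ~1e-6)."""
        pieces: List[float]
        if self.kind == "uniform_soft":
            pieces = [
                scipy.integrate.quad(self.pdf, -np.inf, self.t_L)[0],
                scipy.integrate.quad(self.pdf, self.t_L, self.t_U)[0],
                scipy.integrate.quad(self.pdf, self.t_U, np.inf)[0],
            ]
        else:
            far = self.t_L * (1.0 + (self.p or 0)) + 50.0 * (self.c or 1) * self.t_L
            pieces = [
                scipy.integrate.quad(self.pdf, -np.inf, self.t_L)[0],
                scipy.integrate.quad(self.pdf, self.t_L, far, limit=200)[0],
                scipy.integrate.quad(self.pdf, far, np.inf)[0],
            ]
        return float(sum(pieces))


def make_calibration(kind: str, **params: float) -> CalibrationDensity:
    """Construct and validate a calibration density.

    ``uniform_soft``: requires ``t_L < t_U``; optional ``p_L``/``p_U``
    (default hard, i.e. 1e-300).  ``cauchy_lower``: requires ``t_L``,
    offset ``p`` and scale ``c``; optional ``p_L`` (default hard).
    """
    if kind == "uniform_soft":
        t_L, t_U = float(params["t_L"]), float(params["t_U"])
        p_L = float(params.get("p_L", HARD))
        p_U = float(params.get("p_U", HARD))
        if t_L >= t_U:
            raise ValueError(f"t_L ({t_L}) must be < t_U ({t_U})")
        for name, m in (("p_L", p_L), ("p_U", p_U)):
            if not 0.0 <= m < 0.5:
                raise ValueError(f"{name} must lie in [0, 0.5), got {m}")
        return CalibrationDensity(kind=kind, t_L=t_L, t_U=t_U, p_L=p_L, p_U=p_U)
    if kind == "cauchy_lower":
        t_L = float(params["t_L"])
        p, c = float(params["p"]), float(params["c"])
        p_L = float(params.get("p_L", HARD))
        if t_L <= 0:
            raise ValueError("t_L must be > 0")
        if p < 0 or c <= 0:
            raise ValueError("offset p must be >= 0 and scale c > 0")
        if not 0.0 <= p_L < 0.5:
            raise ValueError(f"p_L must lie in [0, 0.5), got {p_L}")
        return CalibrationDensity(kind=kind, t_L=t_L, p_L=p_L, p=p, c=c)
    raise ValueError(f"unknown calibration kind {kind!r}")


def tail_mass(cal: CalibrationDensity, side: str) -> float:
    """Numerically integrated mass beyond the stated bound.

    ``lower``: mass below ``t_L``; ``upper``: mass above ``t_U`` (defined
    for ``uniform_soft`` only — a Cauchy lower bound is unbounded above by
    design, so asking for its upper tail is an error).
    """
    if side == "lower":
        return float(scipy.integrate.quad(cal.pdf, -np.inf, cal.t_L)[0])
    if side == "upper":
        if cal.kind != "uniform_soft":
            raise ValueError(
                "cauchy_lower calibrations are unbounded above by design; "
                "no upper tail mass is defined"
            )
        return float(scipy.integrate.quad(cal.pdf, cal.t_U, np.inf)[0])
    raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")


def sample(cal: CalibrationDensity, n: int, seed: int) -> np.ndarray:
    """Module-level alias for :meth:`CalibrationDensity.sample`."""
    return cal.sample(n, seed)


# ---------------------------------------------------------------------------
# YAML calibration sets
# ---------------------------------------------------------------------------


def load_calibrations(source: Union[str, Mapping]) -> Dict[str, CalibrationDensity]:
    """Load a named calibration set from YAML text or a parsed mapping.

    Schema: ``calibrations:`` a list of entries with ``node``, ``kind`` and
    the kind's parameters (``t_L``, ``t_U``, ``p``, ``c``, ``p_L``, ``p_U``).
    """
    doc = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    entries = doc["calibrations"] if isinstance(doc, dict) else doc
    out: Dict[str, CalibrationDensity] = {}
    for e in entries:
        e = dict(e)
        node = e.pop("node")
        kind = e.pop("kind")
        if node in out:
            raise ValueError(f"duplicate calibration for node {node!r}")
        out[node] = make_calibration(kind, **e)
    return out


def calibration_report(cals: Mapping[str, CalibrationDensity]) -> Dict[str, Dict[str, float]]:
    """Per-node summary: bounds, numerically checked tail masses, total
    integral and the 2.5/50/97.5% quantiles."""
    report: Dict[str, Dict[str, float]] = {}
    for node, cal in cals.items():
        q = cal.ppf(np.array([0.025, 0.5, 0.975]))
        entry = {
            "kind": cal.kind,
            "t_L": cal.t_L,
            "integral": cal.integral(),
            "lower_tail_mass": tail_mass(cal, "lower"),
            "q2.5": float(q[0]),
            "median": float(q[1]),
            "q97.5": float(q[2]),
        }
        if cal.kind == "uniform_soft":
            entry["t_U"] = cal.t_U
            entry["upper_tail_mass"] = tail_mass(cal, "upper")
        else:
            entry["p"] = cal.p
            entry["c"] = cal.c
        report[node] = entry
    return report
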
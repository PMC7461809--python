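"""Small quantitative models supporting the biochemical assays.

Size-exclusion partition coefficients and oligomer-state calls,
transformation-efficiency fold restriction, dilution-series relative
selectivity, and digestion-ensemble summary statistics (penetrance
recovery, ds:ss break ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import InputError

__all__ = [
    "SecMeasurement",
    "SecStandard",
    "SecCurve",
    "FoldRestriction",
    "EnsembleSummary",
    "kav",
    "fit_sec_curve",
    "estimate_oligomer",
    "fold_restriction",
    "relative_selectivity",
    "ensemble_summary",
]


@dataclass(frozen=True)
class SecMeasurement:
    """One size-exclusion run: elution, void and total column volumes (ml)."""

    ve: float
    vo: float
    vt: float


@dataclass(frozen=True)
class SecStandard:
    """A calibration standard: name, mass (kDa) and measured Kav."""

    name: str
    mass: float
    kav: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise InputError(f"{self.name}: mass must be positive")
        if not 0.0 <= self.kav <= 1.0:
            raise InputError(f"{self.name}: Kav {self.kav} outside [0, 1]")


@dataclass
class SecCurve:
    """Least-squares calibration line Kav = slope * log10(mass) + intercept."""

    slope: float
    intercept: float
    residuals: tuple[float, ...]

    def mass_at(self, kav_value: float) -> float:
        """Invert the calibration: apparent mass (kDa) at a given Kav."""
        if self.slope == 0:
            raise InputError("degenerate calibration (zero slope)")
        return 10 ** ((kav_value - self.intercept) / self.slope)


@dataclass(frozen=True)
class FoldRestriction:
    """Fold restriction, possibly censored by the plating detection limit."""

    fold: float
    censored: bool = False

    def __str__(self) -> str:
        return (">" if self.censored else "") + f"{self.fold:g}"


@dataclass(frozen=True)
class EnsembleSummary:
    penetrance_estimate: float
    ds_ss_ratio: float  # math.inf when no nicks observed
    n_ds: int
    n_nicks: int


def kav(m: SecMeasurement) -> float:
    """Partition coefficient Kav = (ve - vo) / (vt - vo).

    0 for a void-excluded species, 1 for a fully included one; invariant
    under a common rescaling of all three volumes.
    """
    if m.vt <= m.vo:
        raise InputError(f"vt ({m.vt}) must exceed vo ({m.vo})")
    return (m.ve - m.vo) / (m.vt - m.vo)


def fit_sec_curve(standards: Sequence[SecStandard]) -> SecCurve:
    """Ordinary least squares of Kav against log10(mass), unweighted."""
    if len(standards) < 2:
        raise InputError("need at least two calibration standards")
    x = np.log10([s.mass for s in standards])
    y = np.array([s.kav for s in standards])
    if np.allclose(x, x[0]):
        raise InputError("standards must have distinct masses")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return SecCurve(float(slope), float(intercept), tuple(float(r) for r in resid))


def estimate_oligomer(
    mr: float,
    monomer: float,
    bands: dict[str, tuple[float, float]] | None = None,
) -> tuple[float, str]:
    """Oligomeric-state call from apparent vs monomer mass.

    The default bands classify ratio in [0.75, 1.25) as monomer and
    [1.5, 2.5) as dimer; the dimer band deliberately reaches down to 1.5
    so that compact dimers eluting light (e.g. an apparent 54.4 kDa for a
    33.4 kDa monomer, ratio ~1.63) are called dimer rather than ambiguous.
    Ratios of 2.5 and above are "higher"; gaps between bands are
    "ambiguous".
    """
    if mr <= 0 or monomer <= 0:
        raise InputError("masses must be positive")
    ratio = mr / monomer
    bands = bands or {"monomer": (0.75, 1.25), "dimer": (1.5, 2.5)}
    for state, (lo, hi) in bands.items():
        if lo <= ratio < hi:
            return ratio, state
    if ratio >= max(hi for _, hi in bands.values()):
        return ratio, "higher"
    return ratio, "ambiguous"


def fold_restriction(
    control_efficiency: float,
    test_efficiency: float,
    detection_limit: float | None = None,
) -> FoldRestriction:
    """Fold restriction = control / test transformation efficiency (cfu/ug).

    With zero transformants on the test host the fold is censored at
    control / detection_limit (the limit implied by the plated amount,
    e.g. <20 cfu/ug) and reported as a lower bound.
    """
    if control_efficiency <= 0:
        raise InputError("control efficiency must be positive")
    if test_efficiency < 0:
        raise InputError("test efficiency must be non-negative")
    if test_efficiency == 0:
        if not detection_limit or detection_limit <= 0:
            raise InputError("zero test efficiency needs a positive detection_limit")
        return FoldRestriction(control_efficiency / detection_limit, censored=True)
    return FoldRestriction(control_efficiency / test_efficiency)


def relative_selectivity(
    endpoint_modified: int,
    endpoint_unmodified: int,
    dilution_factor: float = 2.0,
    interval_censored: bool = False,
) -> tuple[float, float]:
    """Selectivity fold range from serial-dilution digestion endpoints.

    Endpoints are the last dilution steps with visible digestion on the
    modified and unmodified substrates; the selectivity is
    ``dilution_factor ** delta_steps``.  When endpoints are
    interval-censored by one step the bracketing range
    ``[f**delta, f**(delta+1)]`` is returned (e.g. 8- to 16-fold at
    factor 2 and delta between 3 and 4).
    """
    if endpoint_modified < 0 or endpoint_unmodified < 0:
        raise InputError("dilution steps must be non-negative")
    if dilution_factor <= 1:
        raise InputError("dilution factor must exceed 1")
    delta = endpoint_modified - endpoint_unmodified
    lo = dilution_factor ** delta
    hi = dilution_factor ** (delta + 1) if interval_censored else lo
    return (lo, hi)


def ensemble_summary(ensemble: Sequence[Sequence], n_sites: int) -> EnsembleSummary:
    """Penetrance estimate and ds:ss break ratio of a digestion ensemble.

    ``penetrance_estimate`` is the fraction of the molecule's ``n_sites``
    recognition sites that fired at least once anywhere in the ensemble —
    an estimator of the modified-site fraction under complete digestion
    (firing probability ~1).  ``ds_ss_ratio`` is total ds cuts over total
    nicks; with zero nicks it is reported infinite with the counts kept
    for context.
    """
    if n_sites <= 0:
        raise InputError("n_sites must be positive")
    fired: set[int] = set()
    n_ds = n_nicks = 0
    for events in ensemble:
        for ev in events:
            if ev.site_ref is not None:
                fired.add(ev.site_ref.start)
            if ev.kind == "ds_cut":
                n_ds += 1
            else:
                n_nicks += 1
    ratio = n_ds / n_nicks if n_nicks else math.inf
    return EnsembleSummary(len(fired) / n_sites, ratio, n_ds, n_nicks)
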
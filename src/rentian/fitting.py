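"""Detecting the Rent power-law region and fitting its exponents.

The Rent characteristic of a real network deviates from the power law
``P = k B^p`` at both ends.  At large module sizes (few modules) the
rule overestimates connectivity — Region II; at the smallest modules it
can underestimate — Region III; the power law holds on the remaining
Region I.

Region II is detected through a bifurcation phenomenon: a sample of
degree-preserving randomizations of the network shares the empirical
characteristic at small scales but splits away from it at large scales.
The dispersion of the sample's log-average external-connection counts
at fixed box size, measured by the coefficient of variation ``c``,
quantifies the split; Region II is every scale from the first crossing
of ``c >= beta`` upward (``beta = 0.1`` by default).

Region III, when requested, is trimmed greedily: while the smallest-B
point lies above the fitted line and dropping it raises the coefficient
of determination R² by more than ``rho`` (default 1e-3), it is moved to
Region III.

The Rent exponent ``p`` is then the OLS slope of log10 P on log10 B
over Region I, and the sensitivity exponent ``alpha`` is the OLS slope
of the pooled randomized log10 P' on the matched empirical log10 P
(``P' = K P^alpha``), a measure of how strongly randomization inflates
the network's interconnection complexity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .characteristic import RentCharacteristic, covering_characteristic
from .randomize import RandomModelSpec, generate_ensemble

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleCharacteristic",
    "RegionSegmentation",
    "RentFit",
    "SensitivityFit",
    "ensemble_characteristic",
    "dispersion_profile",
    "segment_regions",
    "fit_rent",
    "fit_sensitivity",
]


@dataclass
class EnsembleCharacteristic:
    """Per-replicate Rent characteristics of a null-model sample."""

    model: str
    characteristics: list[RentCharacteristic]
    dispersion: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.dispersion and len(self.characteristics) >= 2:
            self.dispersion = dispersion_profile(self.characteristics)


@dataclass
class RegionSegmentation:
    """Assignment of usable scales to Regions I, II and III."""

    beta: float
    rho: float
    region_I: tuple[int, ...]
    region_II: tuple[int, ...]
    region_III: tuple[int, ...]
    delta_trace: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "rho": self.rho,
            "region_I": list(self.region_I),
            "region_II": list(self.region_II),
            "region_III": list(self.region_III),
            "delta_trace": self.delta_trace,
        }


@dataclass
class RentFit:
    """OLS fit of Rent's rule P = k B^p in log-log coordinates."""

    p: float
    k: float
    std_err: float
    r_squared: float
    p_value: float
    n_points: int

    def as_dict(self) -> dict:
        return {
            "p": self.p,
            "k": self.k,
            "std_err": self.std_err,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n_points": self.n_points,
        }


@dataclass
class SensitivityFit:
    """Fit of P' = K P^alpha between randomized and empirical scaling."""

    alpha: float
    big_K: float
    std_err: float
    n_points: int = 0

    def as_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "big_K": self.big_K,
            "std_err": self.std_err,
            "n_points": self.n_points,
        }


def ensemble_characteristic(
    g: nx.Graph,
    spec: RandomModelSpec,
    repetitions: int = 1,
    covering_seed: int | None = None,
) -> EnsembleCharacteristic:
    """Box-covering characteristics of every replicate of a null model.

    Each replicate is partitioned once by default (``repetitions=1``):
    sample-level averaging already damps the coloring noise.  SA
    replicates occasionally disconnect; boxes then never span
    components, which preserves N and the per-module P semantics.
    """
    graphs = generate_ensemble(g, spec)
    chars = []
    for rep, h in enumerate(graphs):
        seed = covering_seed if covering_seed is not None else h.graph.get("seed", rep)
        chars.append(
            covering_characteristic(
                h, seed=int(seed) % (2**31), repetitions=repetitions, allow_disconnected=True
            )
        )
    return EnsembleCharacteristic(model=spec.model, characteristics=chars)


def dispersion_profile(
    characteristics: list[RentCharacteristic] | EnsembleCharacteristic,
    log: bool = True,
) -> dict[int, float]:
    """Coefficient of variation of the sample's P values at each scale.

    At each box size ``b`` represented with ``P > 0`` in at least two
    replicates, ``c(b)`` is the sample standard deviation of
    ``log10 P_i(b)`` over replicates divided by its mean (``log=False``
    uses the plain P values instead).  Scales where the mean of the
    logs is not positive — all replicate averages at or below one
    external edge — have no meaningful CV and are flagged and skipped.
    """
    if isinstance(characteristics, EnsembleCharacteristic):
        characteristics = characteristics.characteristics
    if len(characteristics) < 2:
        raise ValueError("dispersion needs at least two replicates")
    values: dict[int, list[float]] = {}
    for char in characteristics:
        for pt in char.points:
            if pt.b is None or pt.P <= 0:
                continue
            values.setdefault(pt.b, []).append(
                math.log10(pt.P) if log else pt.P
            )
    out: dict[int, float] = {}
    for b in sorted(values):
        vals = values[b]
        if len(vals) < 2:
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1))
        if mean <= 0:
            logger.warning("dispersion undefined at b=%d (mean log10 P = %.3g <= 0)", b, mean)
            continue
        out[b] = sd / mean
    return out


def _ols_loglog(points) -> tuple[float, float, float, float, float]:
    x = np.log10([pt.B for pt in points])
    y = np.log10([pt.P for pt in points])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: all module sizes B identical")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.stderr, res.rvalue**2, res.pvalue


def segment_regions(
    emp: RentCharacteristic,
    ens: EnsembleCharacteristic | dict[int, float],
    beta: float = 0.1,
    rho: float = 1e-3,
    trim_region_III: bool = False,
    underestimate_above: bool = True,
) -> RegionSegmentation:
    """Split the usable scales of a characteristic into Regions I/II/III.

    Parameters
    ----------
    emp:
        Empirical characteristic (scales labelled by box size ``b``).
    ens:
        Ensemble of the same covering scales, or a precomputed
        dispersion profile ``b -> c``.
    beta:
        CV threshold: Region II is upward-closed from the smallest
        ``b*`` with ``c(b*) >= beta`` (the bifurcation widens with b, so
        occasional dips above the crossing do not reopen Region I).
    rho:
        Minimum R² increment for a Region III removal.
    trim_region_III:
        Whether to trim underestimated small-B points at all.
    underestimate_above:
        Sign convention for "the power law underestimates": the
        empirical point lies above the fitted line.  Set ``False`` to
        trim points lying below instead.
    """
    c = ens if isinstance(ens, dict) else ens.dispersion
    usable = [pt for pt in emp.points if pt.P > 0 and pt.b is not None]
    usable.sort(key=lambda pt: pt.b)
    crossing = None
    for pt in usable:
        if c.get(pt.b) is not None and c[pt.b] >= beta:
            crossing = pt.b
            break
    # scales past the last one the ensemble can resolve are the extreme form
    # of the bifurcation: every replicate's covering has already collapsed
    # (P' = 0 there), so the dispersion is off the scale
    beyond = [pt.b for pt in usable if pt.b > max(c)] if c else []
    candidates = ([crossing] if crossing is not None else []) + beyond
    crossing = min(candidates) if candidates else None
    region_II = tuple(pt.b for pt in usable if crossing is not None and pt.b >= crossing)
    remaining = [pt for pt in usable if pt.b not in set(region_II)]

    region_III: list[int] = []
    delta_trace: list[float] = []
    if trim_region_III:
        # smallest B first; stop as soon as a removal fails the criterion
        remaining.sort(key=lambda pt: pt.B)
        while len(remaining) > 3:
            slope, intercept, _, r2, _ = _ols_loglog(remaining)
            head = remaining[0]
            resid = math.log10(head.P) - (intercept + slope * math.log10(head.B))
            above = resid > 0 if underestimate_above else resid < 0
            if not above:
                break
            _, _, _, r2_new, _ = _ols_loglog(remaining[1:])
            delta = r2_new - r2
            if delta <= rho:
                break
            region_III.append(head.b)
            delta_trace.append(delta)
            remaining = remaining[1:]

    region_I = tuple(pt.b for pt in remaining)
    if len(region_I) < 3:
        raise ValueError(
            f"only {len(region_I)} scales left for Region I; "
            "consider a smaller beta or more covering scales"
        )
    return RegionSegmentation(
        beta=beta,
        rho=rho,
        region_I=region_I,
        region_II=region_II,
        region_III=tuple(region_III),
        delta_trace=delta_trace,
    )


def fit_rent(emp: RentCharacteristic, region: RegionSegmentation | None = None) -> RentFit:
    """Fit Rent's rule over Region I (or over all positive-P points).

    Ordinary least squares of log10 P on log10 B; the slope is the Rent
    exponent ``p``, the intercept gives ``k = 10^intercept``, and the
    slope's two-sided t-test p-value measures significance.
    """
    pts = emp.positive()
    if region is not None:
        keep = set(region.region_I)
        pts = [pt for pt in pts if pt.b in keep]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 points with P > 0 to fit, got {len(pts)}")
    slope, intercept, stderr, r2, pval = _ols_loglog(pts)
    return RentFit(
        p=float(slope),
        k=float(10**intercept),
        std_err=float(stderr),
        r_squared=float(r2),
        p_value=float(pval),
        n_points=len(pts),
    )


def fit_sensitivity(
    emp: RentCharacteristic,
    ens: EnsembleCharacteristic,
    region: RegionSegmentation | None = None,
) -> SensitivityFit:
    """Fit P' = K P^alpha between a null-model sample and the network.

    Pools every replicate's (b, P') point whose scale b also appears in
    the empirical characteristic (restricted to Region I when a
    segmentation is given — for bisection-sourced characteristics all
    scales are typically used) and regresses log10 P' on the matched
    empirical log10 P.
    """
    emp_at = {pt.b: pt.P for pt in emp.positive() if pt.b is not None}
    if region is not None:
        keep = set(region.region_I)
        emp_at = {b: P for b, P in emp_at.items() if b in keep}
    xs, ys = [], []
    for char in ens.characteristics:
        for pt in char.points:
            if pt.b in emp_at and pt.P > 0:
                xs.append(math.log10(emp_at[pt.b]))
                ys.append(math.log10(pt.P))
    if len(set(xs)) < 3:
        raise ValueError(f"need >= 3 matched scales, got {len(set(xs))}")
    res = stats.linregress(xs, ys)
    return SensitivityFit(
        alpha=float(res.slope),
        big_K=float(10**res.intercept),
        std_err=float(res.stderr),
        n_points=len(xs),
    )
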
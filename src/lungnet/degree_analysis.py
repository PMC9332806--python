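"""Degree distributions, network metrics, and distribution-shape fits.

The texture signature of a layer is the histogram of node degrees of its
pixel graph. Aerated, quietly varying parenchyma produces networks whose
degree-count curve is well described by a logarithmic function
``y = a·ln(k) + b``; proliferative pathology (inflammation, fibrosis)
produces humped distributions best captured by a low-order polynomial, while
a pure power law ``y = a·k^b`` fits normal lung poorly. Comparing the
coefficient of determination R² across these families, together with three
size metrics (degree sum, mean degree, maximum degree), separates normal
from diseased texture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, UndefinedStatisticError
from .hu_layers import LayerMask
from .pixel_graph import GraphParams, PixelGraph, build_graph

FIT_FAMILIES = ("logarithmic", "power", "polynomial")

#: Observed polynomial-degree range for the pathological fits.
POLY_DEGREE_RANGE = (2, 8)

#: Smallest / tie tolerance used when selecting a polynomial degree.
_ADJ_R2_TIE = 1e-12


@dataclass(frozen=True)
class DegreeDistribution:
    """(degree, node count) pairs of one pixel graph."""

    degrees: np.ndarray
    counts: np.ndarray
    n_nodes: int
    n_edges: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"degree": self.degrees, "count": self.counts})

    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairs with degree >= 1 (the fitting domain; ln 0 is undefined)."""
        keep = self.degrees >= 1
        return self.degrees[keep], self.counts[keep]


@dataclass(frozen=True)
class NetworkMetrics:
    """Size/complexity summary of one pixel graph.

    total_count is the degree sum (= 2|E|), average_count the mean degree
    (0 for an empty graph), max_degree the largest node degree.
    """

    total_count: int
    average_count: float
    max_degree: int


@dataclass(frozen=True)
class FitResult:
    """A fitted degree-count curve.

    ``coefficients``: (a, b) for logarithmic ``a·ln k + b`` and power
    ``a·k^b``; highest-power-first for polynomial. R² is always computed on
    the original count scale so families are comparable.
    """

    family: str
    coefficients: tuple[float, ...]
    r2: float
    poly_degree: int | None = None
    n_points: int = 0

    def predict(self, k: np.ndarray) -> np.ndarray:
        k = np.asarray(k, dtype=float)
        if self.family == "logarithmic":
            a, b = self.coefficients
            return a * np.log(k) + b
        if self.family == "power":
            a, b = self.coefficients
            return a * np.power(k, b)
        return np.polyval(self.coefficients, k)


def degree_distribution(g: PixelGraph) -> DegreeDistribution:
    """Exact histogram of node degrees; empty graph gives an empty pair list."""
    deg = g.degrees()
    if deg.size == 0:
        return DegreeDistribution(
            degrees=np.zeros(0, dtype=int),
            counts=np.zeros(0, dtype=int),
            n_nodes=0,
            n_edges=0,
        )
    degrees, counts = np.unique(deg, return_counts=True)
    return DegreeDistribution(
        degrees=degrees.astype(int),
        counts=counts.astype(int),
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
    )


def network_metrics(g: PixelGraph) -> NetworkMetrics:
    deg = g.degrees()
    if deg.size == 0:
        return NetworkMetrics(total_count=0, average_count=0.0, max_degree=0)
    return NetworkMetrics(
        total_count=int(deg.sum()),
        average_count=float(deg.mean()),
        max_degree=int(deg.max()),
    )


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise UndefinedStatisticError("R² undefined: counts are constant")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_distribution(
    d: DegreeDistribution,
    family: str,
    poly_degree_range: tuple[int, int] = POLY_DEGREE_RANGE,
) -> FitResult:
    """Least-squares fit of node count versus degree for one family.

    Degree-0 nodes are excluded (the logarithm is undefined there). The
    power family is fitted by log–log linear least squares — deterministic,
    no initialisation — with R² recomputed on the original count scale. The
    polynomial degree is chosen inside ``poly_degree_range`` by maximum
    adjusted R², ties going to the lowest degree; candidate degrees are
    capped at ``n − 2`` so the adjustment stays defined.
    """
    if family not in FIT_FAMILIES:
        raise DomainError(f"unknown fit family {family!r}")
    k, y = d.positive()
    k = k.astype(float)
    y = y.astype(float)
    if np.unique(k).size < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct positive degrees, got {np.unique(k).size}"
        )

    if family == "logarithmic":
        X = np.column_stack([np.log(k), np.ones_like(k)])
        (a, b), *_ = np.linalg.lstsq(X, y, rcond=None)
        return FitResult("logarithmic", (float(a), float(b)),
                         _r2(y, a * np.log(k) + b), n_points=k.size)

    if family == "power":
        X = np.column_stack([np.log(k), np.ones_like(k)])
        (b, ln_a), *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
        a = float(np.exp(ln_a))
        return FitResult("power", (a, float(b)),
                         _r2(y, a * np.power(k, b)), n_points=k.size)

    lo, hi = poly_degree_range
    candidates = [deg for deg in range(lo, hi + 1) if deg <= k.size - 2]
    if not candidates:
        raise InsufficientDataError(
            f"need >= {lo + 2} positive-degree points for a degree-{lo} "
            f"polynomial with adjusted R², got {k.size}"
        )
    best: tuple[float, int, np.ndarray, float] | None = None
    n = k.size
    for deg in candidates:
        coeffs = np.polyfit(k, y, deg)
        r2 = _r2(y, np.polyval(coeffs, k))
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - deg - 1)
        if best is None or adj > best[0] + _ADJ_R2_TIE:
            best = (adj, deg, coeffs, r2)
    _, deg, coeffs, r2 = best
    return FitResult("polynomial", tuple(float(c) for c in coeffs), r2,
                     poly_degree=deg, n_points=n)


def best_fit(
    d: DegreeDistribution,
    families: Sequence[str] = FIT_FAMILIES,
) -> FitResult:
    """The family with the highest R² on the original scale."""
    results = []
    for fam in families:
        try:
            results.append(fit_distribution(d, fam))
        except (InsufficientDataError, UndefinedStatisticError):
            continue
    if not results:
        raise InsufficientDataError("no family could be fitted")
    return max(results, key=lambda r: r.r2)


def rd_sweep(
    layer: LayerMask,
    rd_values: Iterable[float] = range(1, 9),
    params: GraphParams | None = None,
    families: Sequence[str] = ("logarithmic", "power"),
) -> pd.DataFrame:
    """Rebuild the layer's graph at each radius and fit each family.

    Returns a long table (rd, family, r2, n_nodes, n_edges); cells whose fit
    is impossible (too few distinct degrees, constant counts) carry NaN
    rather than aborting the sweep.
    """
    params = params or GraphParams()
    rows = []
    for rd in rd_values:
        if rd <= 0:
            raise DomainError("rd values must be positive")
        g = build_graph(
            layer, GraphParams(rd_max=float(rd), delta_max=params.delta_max)
        )
        d = degree_distribution(g)
        for fam in families:
            try:
                r2 = fit_distribution(d, fam).r2
            except (InsufficientDataError, UndefinedStatisticError):
                r2 = np.nan
            rows.append(
                {"rd": float(rd), "family": fam, "r2": r2,
                 "n_nodes": g.n_nodes, "n_edges": g.n_edges}
            )
    return pd.DataFrame(rows)


def mean_rd_sweep(
    layers: Sequence[LayerMask],
    rd_values: Iterable[float] = range(1, 9),
    params: GraphParams | None = None,
    families: Sequence[str] = ("logarithmic", "power"),
) -> pd.DataFrame:
    """Average the per-layer sweep over a lot: (rd, family, mean_r2, n_fitted)."""
    rd_values = list(rd_values)
    frames = [rd_sweep(layer, rd_values, params, families) for layer in layers]
    stacked = pd.concat(frames, ignore_index=True)
    out = (
        stacked.groupby(["rd", "family"], as_index=False)
        .agg(mean_r2=("r2", "mean"), n_fitted=("r2", "count"))
    )
    return out
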
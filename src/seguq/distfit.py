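"""Characteristic uncertainty distributions from percentile-sweep tables.

A physics quantity Q evaluated on percentile segmentations yields a table
of (P, Q(P)) points — samples of the quantity's uncertainty distribution at
known quantile levels.  The characteristic Normal distribution is specified
by the three standard segmentations alone:

    mean  = Q(50.0)
    sigma = (Q(84.1) - Q(15.9)) / 2

i.e. the median supplies the mean and the symmetric half-width between the
mu+/-sigma percentiles supplies the standard deviation.  Both one-sided
half-widths are kept in the diagnostics so asymmetry stays visible.  The
fit is validated against held-out percentiles: if the characteristic CDF
evaluated at Q(P) strays from P/100 by more than a tolerance (default
0.05), the Normal assumption is poor and a heavier-tailed or bounded family
(beta, half-Cauchy) or the empirical CDF should be used instead.

Alternative families are fitted by least-squares quantile matching
(minimizing sum_P (quantile_family(P/100) - Q(P))^2) with a derivative-free
simplex started from moment-based guesses, since the tables are tiny and
exact quantile data recovers parameters to high precision.

A monotonicity check guards the whole construction: when Q(P) is not
monotone in P — the regime where a handful of percentile segmentations can
fail even to bound the quantity — characteristic fitting requires an
explicit override.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .percentile import STANDARD_PERCENTILES

__all__ = [
    "QuantityTable",
    "CharacteristicDistribution",
    "MonotonicityError",
    "FitError",
    "fit_characteristic_normal",
    "characteristic_cdf",
    "characteristic_quantile",
    "assess_characteristic_fit",
    "fit_alternative",
    "check_monotonicity",
    "MonotonicityReport",
]

FAMILIES = ("normal", "beta", "half_cauchy", "empirical")
DEFAULT_CDF_TOL = 0.05
_STD_TOL = 1e-9  # matching tolerance for locating the standard percentiles


class MonotonicityError(ValueError):
    """The table is non-monotone where a monotone construction is required."""


class FitError(RuntimeError):
    def __init__(self, msg, best_params=None):
        super().__init__(msg)
        self.best_params = best_params


@dataclass
class QuantityTable:
    """Rows of (percentile P, quantity value Q(P)) for one physics quantity."""

    percentiles: np.ndarray
    values: np.ndarray
    quantity: str = ""
    source: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.percentiles = np.asarray(self.percentiles, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.percentiles.shape != self.values.shape or self.percentiles.ndim != 1:
            raise ValueError("percentiles and values must be equal-length 1D arrays")
        if np.any((self.percentiles <= 0) | (self.percentiles >= 100)):
            raise ValueError("percentiles must lie strictly in (0, 100)")
        if len(np.unique(self.percentiles)) != len(self.percentiles):
            raise ValueError("percentiles must be unique")
        order = np.argsort(self.percentiles)
        self.percentiles = self.percentiles[order]
        self.values = self.values[order]

    def __len__(self):
        return len(self.percentiles)

    def value_at(self, P: float) -> float:
        hit = np.isclose(self.percentiles, P, atol=_STD_TOL, rtol=0.0)
        if not hit.any():
            raise KeyError(f"percentile {P} not tabulated")
        return float(self.values[hit][0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"percentile": self.percentiles, "value": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, quantity: str = "") -> "QuantityTable":
        df = pd.read_csv(path)
        return cls(percentiles=df["percentile"].to_numpy(),
                   values=df["value"].to_numpy(), quantity=quantity,
                   source={"path": str(path)})

    @classmethod
    def from_results(cls, results, quantity: str) -> "QuantityTable":
        rows = [(r.percentile, r.value) for r in results if r.quantity == quantity]
        if not rows:
            raise ValueError(f"no results for quantity {quantity!r}")
        P, Q = zip(*rows)
        return cls(percentiles=np.array(P), values=np.array(Q), quantity=quantity)


@dataclass
class CharacteristicDistribution:
    """A parametric (or empirical) estimate of the quantity's uncertainty CDF."""

    family: str
    params: dict
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "normal" and self.params["sigma"] < 0:
            raise ValueError("normal sigma must be >= 0")

    # frozen scipy distribution backing the parametric families
    def _frozen(self):
        p = self.params
        if self.family == "normal":
            return stats.norm(loc=p["mean"], scale=p["sigma"])
        if self.family == "beta":
            return stats.beta(p["a"], p["b"], loc=p["loc"], scale=p["scale"])
        if self.family == "half_cauchy":
            return stats.halfcauchy(loc=p["loc"], scale=p["scale"])
        raise AssertionError(self.family)

    def cdf(self, q):
        q = np.asarray(q, dtype=np.float64)
        if self.family == "empirical":
            v, pr = self.params["values"], self.params["probs"]
            out = np.interp(q, v, pr, left=0.0, right=1.0)
            return out if out.ndim else float(out)
        if self.family == "normal" and self.params["sigma"] == 0.0:
            out = (q >= self.params["mean"]).astype(np.float64)
            return out if out.ndim else float(out)
        out = self._frozen().cdf(q)
        return out if np.ndim(out) else float(out)

    def quantile(self, p):
        p_arr = np.asarray(p, dtype=np.float64)
        if np.any((p_arr <= 0) | (p_arr >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        if self.family == "empirical":
            v, pr = self.params["values"], self.params["probs"]
            out = np.interp(p_arr, pr, v, left=v[0], right=v[-1])
            return out if out.ndim else float(out)
        if self.family == "normal" and self.params["sigma"] == 0.0:
            out = np.full_like(p_arr, self.params["mean"])
            return out if out.ndim else float(out)
        out = self._frozen().ppf(p_arr)
        return out if np.ndim(out) else float(out)

    def to_json(self, path=None) -> str:
        payload = {
            "family": self.family,
            "params": {k: (np.asarray(v).tolist() if isinstance(v, np.ndarray)
                           else v) for k, v in self.params.items()},
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2, sort_keys=True) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def characteristic_cdf(dist: CharacteristicDistribution, q):
    """CDF of the characteristic distribution at value(s) q."""
    return dist.cdf(q)


def characteristic_quantile(dist: CharacteristicDistribution, p):
    """Quantile (inverse CDF) of the characteristic distribution at level(s) p."""
    return dist.quantile(p)


def fit_characteristic_normal(table: QuantityTable,
                              allow_nonmonotone: bool = False
                              ) -> CharacteristicDistribution:
    """Normal estimate from the three standard segmentations.

    Requires P in {15.9, 50.0, 84.1}.  A decreasing quantity (negative raw
    half-width) is handled by taking the magnitude and flagging the
    orientation.  Non-monotone tables are refused unless explicitly
    overridden, per the monotonicity-guard policy.
    """
    missing = [P for P in STANDARD_PERCENTILES
               if not np.isclose(table.percentiles, P, atol=_STD_TOL).any()]
    if missing:
        raise ValueError(f"table is missing standard percentile(s) {missing}")
    if len(table) >= 3 and not allow_nonmonotone:
        report = check_monotonicity(table)
        if not report.monotone:
            raise MonotonicityError(
                "quantity is non-monotone in percentile; pass "
                "allow_nonmonotone=True to force a characteristic fit or use "
                "the empirical family"
            )
    q_lo = table.value_at(15.9)
    q_mid = table.value_at(50.0)
    q_hi = table.value_at(84.1)
    half = (q_hi - q_lo) / 2.0
    sigma = abs(half)
    diagnostics = {
        "upper_half_width": q_hi - q_mid,
        "lower_half_width": q_mid - q_lo,
        "decreasing_orientation": bool(half < 0),
        "degenerate": bool(sigma == 0.0),
    }
    return CharacteristicDistribution(
        family="normal", params={"mean": q_mid, "sigma": sigma},
        diagnostics=diagnostics,
    )


def assess_characteristic_fit(dist: CharacteristicDistribution,
                              table: QuantityTable,
                              tol: float = DEFAULT_CDF_TOL) -> dict:
    """Held-out validation of a characteristic fit.

    For each tabulated percentile beyond the standard three, measures the
    absolute discrepancy |cdf(Q(P)) - P/100|.  The fit passes when the
    maximum discrepancy stays below ``tol``.
    """
    is_std = np.zeros(len(table), dtype=bool)
    for P in STANDARD_PERCENTILES:
        is_std |= np.isclose(table.percentiles, P, atol=_STD_TOL)
    held_P = table.percentiles[~is_std]
    held_Q = table.values[~is_std]
    if held_P.size == 0:
        raise ValueError("no held-out rows: table contains only the standard "
                         "percentiles")
    disc = np.abs(np.asarray(dist.cdf(held_Q)) - held_P / 100.0)
    return {
        "held_out_percentiles": held_P.tolist(),
        "discrepancies": disc.tolist(),
        "max_discrepancy": float(disc.max()),
        "mean_discrepancy": float(disc.mean()),
        "tolerance": float(tol),
        "passed": bool(disc.max() < tol),
    }


# ---------------------------------------------------------------------------
# Alternative families by least-squares quantile matching
# ---------------------------------------------------------------------------


def _quantile_loss(quantile_fn, p_levels, q_values):
    def loss(theta):
        try:
            pred = quantile_fn(theta, p_levels)
        except (ValueError, FloatingPointError):
            return np.inf
        if not np.all(np.isfinite(pred)):
            return np.inf
        return float(np.sum((pred - q_values) ** 2))
    return loss


def _simplex(loss, starts):
    best = None
    for x0 in starts:
        res = optimize.minimize(loss, x0, method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-20,
                                         "maxiter": 20000, "maxfev": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best


def fit_alternative(table: QuantityTable, family: str,
                    support: tuple[float, float] | None = None,
                    seed: int = 0) -> CharacteristicDistribution:
    """Fit a non-Normal family to a percentile table.

    Parameters minimize the sum of squared quantile residuals
    sum_P (quantile_family(P/100) - Q(P))^2, via Nelder-Mead simplex with
    three restarts from (perturbed) moment-based starting points.  The
    ``empirical`` family needs no optimization: it is the monotone linear
    interpolant of (Q(P), P/100).

    Beta support defaults to [0, 1.1 * max(Q)] (a bounded-below family is
    the natural choice for positive quantities such as permeability) unless
    given explicitly; with no support supplied the table must have >= 6
    rows, otherwise >= 4.
    """
    if family not in ("beta", "half_cauchy", "empirical"):
        raise ValueError(f"unsupported alternative family {family!r}")
    p_levels = table.percentiles / 100.0
    q_values = table.values

    if family == "empirical":
        if not np.all(np.diff(q_values) >= 0):
            raise MonotonicityError(
                "empirical CDF requires Q nondecreasing in P; run "
                "check_monotonicity for the offending rows"
            )
        return CharacteristicDistribution(
            family="empirical",
            params={"values": q_values.copy(), "probs": p_levels.copy()},
            diagnostics={"n_points": len(table)},
        )

    min_rows = 4 if (family == "half_cauchy" or support is not None) else 6
    if len(table) < min_rows:
        raise ValueError(
            f"family {family!r} needs >= {min_rows} rows "
            f"({len(table)} given)"
        )

    rng = np.random.default_rng(seed)

    if family == "half_cauchy":
        # median = loc + scale, IQR = (tan(3pi/8) - tan(pi/8)) * scale = 2*scale
        med = np.interp(0.5, p_levels, q_values)
        q25 = np.interp(0.25, p_levels, q_values)
        q75 = np.interp(0.75, p_levels, q_values)
        scale0 = max((q75 - q25) / 2.0, 1e-12 + abs(med) * 1e-6)
        loc0 = med - scale0

        def quantile_fn(theta, p):
            loc, log_scale = theta
            return stats.halfcauchy.ppf(p, loc=loc, scale=np.exp(log_scale))

        base = np.array([loc0, np.log(scale0)])
        starts = [base] + [base + rng.normal(scale=[abs(loc0) * 0.05 + 0.05, 0.2])
                           for _ in range(2)]
        loss = _quantile_loss(quantile_fn, p_levels, q_values)
        res = _simplex(loss, starts)
        loc, scale = res.x[0], float(np.exp(res.x[1]))
        params = {"loc": float(loc), "scale": scale}
    else:  # beta
        if support is None:
            hi = float(q_values.max())
            support = (0.0, hi * 1.1 if hi > 0 else 1.0)
        lo, hi = float(support[0]), float(support[1])
        if not lo < hi:
            raise ValueError(f"beta support must satisfy lower < upper, got "
                             f"{support}")
        u = np.clip((q_values - lo) / (hi - lo), 1e-9, 1 - 1e-9)
        m, v = float(u.mean()), float(max(u.var(), 1e-6))
        common = m * (1 - m) / v - 1.0
        a0, b0 = max(m * common, 0.2), max((1 - m) * common, 0.2)

        def quantile_fn(theta, p):
            a, b = np.exp(theta)
            return stats.beta.ppf(p, a, b, loc=lo, scale=hi - lo)

        base = np.log([a0, b0])
        starts = [base] + [base + rng.normal(scale=0.3, size=2)
                           for _ in range(2)]
        loss = _quantile_loss(quantile_fn, p_levels, q_values)
        res = _simplex(loss, starts)
        a, b = np.exp(res.x)
        params = {"a": float(a), "b": float(b), "loc": lo, "scale": hi - lo}

    if not np.isfinite(res.fun):
        raise FitError(f"quantile-matching fit for {family!r} diverged",
                       best_params=params)
    diagnostics = {"sse": float(res.fun), "converged": bool(res.success),
                   "n_points": len(table)}
    return CharacteristicDistribution(family=family, params=params,
                                      diagnostics=diagnostics)


@dataclass
class MonotonicityReport:
    """Whether Q(P) behaves monotonically, and whether the mu+/-sigma band holds."""

    monotone: bool
    direction: str  # "nondecreasing", "nonincreasing", "constant" or "none"
    violations: list  # (P_i, P_j) pairs breaking the trend
    band_escapes: list  # percentiles whose value leaves [Q(15.9), Q(84.1)]
    has_standard_band: bool


def check_monotonicity(table: QuantityTable) -> MonotonicityReport:
    """Flag non-monotone sweeps and escapes from the standard-percentile band.

    Two failure modes are reported: Q(P) not monotone in P, and any value at
    a percentile inside (15.9, 84.1) falling outside the closed interval
    spanned by Q(15.9) and Q(84.1) — the regime where bounding uncertainty
    with a handful of segmentations breaks down.
    """
    if len(table) < 3:
        raise ValueError("monotonicity check needs >= 3 rows")
    dq = np.diff(table.values)
    nondec = bool(np.all(dq >= 0))
    noninc = bool(np.all(dq <= 0))
    if nondec and noninc:
        direction = "constant"
    elif nondec:
        direction = "nondecreasing"
    elif noninc:
        direction = "nonincreasing"
    else:
        direction = "none"
    violations = []
    if direction == "none":
        P, Q = table.percentiles, table.values
        sign = 1.0 if Q[-1] >= Q[0] else -1.0
        for i in range(len(table)):
            for j in range(i + 1, len(table)):
                if sign * (Q[j] - Q[i]) < 0:
                    violations.append((float(P[i]), float(P[j])))

    has_band = all(np.isclose(table.percentiles, P, atol=_STD_TOL).any()
                   for P in (15.9, 84.1))
    escapes = []
    if has_band:
        q_lo = table.value_at(15.9)
        q_hi = table.value_at(84.1)
        band_lo, band_hi = min(q_lo, q_hi), max(q_lo, q_hi)
        inside = (table.percentiles > 15.9 + _STD_TOL) & \
                 (table.percentiles < 84.1 - _STD_TOL)
        for P, Q in zip(table.percentiles[inside], table.values[inside]):
            if Q < band_lo or Q > band_hi:
                escapes.append(float(P))

    return MonotonicityReport(monotone=(direction != "none"),
                              direction=direction, violations=violations,
                              band_escapes=escapes, has_standard_band=has_band)
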
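"""Screening statistics: well summaries, RPS normalization, replicate
ranking and hit selection, dose-response IC50 fitting, and screen QC.

The plate-level normalization is the robust percent of samples:
``RPS_i = 100 * S_i / median(S_all)`` where ``S_i`` is a compound well's
readout (% foci-positive by default, mean foci per cell as the alternative)
and the median runs over the compound wells of the same plate — control and
DOX wells are excluded (they are not compounds).  Compounds are ranked by
the mean RPS over replicates and the ``n_select`` (default 12) lowest means
are forwarded as hits.

Dose-response curves are fit with a four-parameter logistic (4PL) on
log-dose; the screen QC comparison between control and hit wells uses an
in-package Mann-Whitney U with exact small-sample p-values.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WellSummary",
    "DoseResponseFit",
    "GroupComparison",
    "summarize_well",
    "summarize_wells",
    "compute_rps",
    "aggregate_and_rank",
    "FourParamLogistic",
    "fit_dose_response",
    "mann_whitney_u",
    "screen_qc",
]

COMPOUND_ROLES = ("compound",)


@dataclass
class WellSummary:
    """Per-well aggregate of classified cells.

    ``pct_foci_positive = 100 * n_pos / (n_pos + n_neg)`` — non-signaling
    cells are excluded from the denominator; with zero signaling cells the
    percentage is missing (NaN), never 0.
    """

    plate: str
    well: str
    role: str
    compound_id: str
    n_pos: int
    n_neg: int
    n_nonsig: int
    pct_foci_positive: float
    mean_foci_per_cell: float = float("nan")
    n_fields: int = 1

    @property
    def n_cells(self) -> int:
        return self.n_pos + self.n_neg + self.n_nonsig

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.pct_foci_positive)


def summarize_well(cell_records: pd.DataFrame, layout_row) -> WellSummary:
    """Summarize the classified cells of one well.

    ``cell_records`` needs a ``class`` (or ``true_class``) column; all rows
    must belong to the single well named by ``layout_row`` (mapping with
    plate/well/role/compound_id).
    """
    col = "class" if "class" in cell_records.columns else "true_class"
    if col not in cell_records.columns:
        raise ValueError("cell records need a 'class' or 'true_class' column")
    if {"plate", "well"}.issubset(cell_records.columns) and len(cell_records):
        span = cell_records[["plate", "well"]].drop_duplicates()
        if len(span) > 1:
            raise ValueError(f"records span multiple wells: {span.to_dict('records')}")
    counts = cell_records[col].value_counts()
    n_pos = int(counts.get("foci_positive", 0))
    n_neg = int(counts.get("foci_negative", 0))
    n_nonsig = int(counts.get("non_signaling", 0))
    denom = n_pos + n_neg
    pct = 100.0 * n_pos / denom if denom > 0 else float("nan")
    n_fields = (
        cell_records["field"].nunique() if "field" in cell_records.columns and len(cell_records) else 1
    )
    return WellSummary(
        plate=str(layout_row["plate"]),
        well=str(layout_row["well"]),
        role=str(layout_row.get("role", "")),
        compound_id=str(layout_row.get("compound_id", "") or ""),
        n_pos=n_pos,
        n_neg=n_neg,
        n_nonsig=n_nonsig,
        pct_foci_positive=pct,
        n_fields=int(max(n_fields, 1)),
    )


def summarize_wells(cells: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Vectorized well summaries for a whole screen (one row per layout
    well, replicate-aware)."""
    keys = [k for k in ("replicate", "plate", "well") if k in layout.columns]
    col = "class" if "class" in cells.columns else "true_class"
    rows = []
    grouped = cells.groupby(keys, sort=False)
    for _, lrow in layout.iterrows():
        key = tuple(lrow[k] for k in keys)
        try:
            grp = grouped.get_group(key if len(key) > 1 else key[0])
        except KeyError:
            grp = cells.iloc[0:0]
        counts = grp[col].value_counts() if len(grp) else {}
        n_pos = int(counts.get("foci_positive", 0))
        n_neg = int(counts.get("foci_negative", 0))
        n_nonsig = int(counts.get("non_signaling", 0))
        denom = n_pos + n_neg
        rows.append(
            {
                **{k: lrow[k] for k in keys},
                "role": lrow.get("role", ""),
                "compound_id": lrow.get("compound_id", ""),
                "n_pos": n_pos,
                "n_neg": n_neg,
                "n_nonsig": n_nonsig,
                "pct_foci_positive": 100.0 * n_pos / denom if denom else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def compute_rps(plate_values: pd.Series) -> pd.Series:
    """RPS for one plate and one replicate: ``100 * S_i / median(S_all)``.

    ``plate_values`` maps compound_id -> readout for the compound wells of a
    single plate.  Missing readouts are excluded from the median and stay
    missing in the output.
    """
    s = pd.Series(plate_values, dtype=float)
    valid = s.dropna()
    if valid.empty:
        raise ValueError("no compound well with a non-missing readout on this plate")
    med = float(valid.median())
    if med == 0:
        raise ValueError("plate median readout is 0; RPS normalization undefined")
    return 100.0 * s / med


def aggregate_and_rank(
    replicate_tables: list[pd.Series],
    n_select: int = 12,
) -> pd.DataFrame:
    """Mean per-compound RPS over replicates, ascending rank, hit flags.

    Ranking is by mean RPS with ties broken by compound_id lexicographic
    order (stable, deterministic); the ``n_select`` lowest means are
    flagged ``selected``.  Compounds missing from a replicate are averaged
    over the replicates where they appear (count recorded in ``n_reps``).
    """
    if n_select < 0:
        raise ValueError("n_select must be >= 0")
    if not replicate_tables:
        raise ValueError("need at least one replicate table")
    frames = []
    for i, tab in enumerate(replicate_tables, start=1):
        s = pd.Series(tab, dtype=float)
        if s.index.duplicated().any():
            dupes = sorted(s.index[s.index.duplicated()].unique())
            raise ValueError(f"duplicate compound_id within replicate {i}: {dupes}")
        frames.append(s.rename(f"rps_rep{i}"))
    table = pd.concat(frames, axis=1)
    table.index.name = "compound_id"
    rps_cols = list(table.columns)
    table["n_reps"] = table[rps_cols].notna().sum(axis=1)
    table["mean_rps"] = table[rps_cols].mean(axis=1, skipna=True)
    table = table.reset_index().sort_values(
        ["mean_rps", "compound_id"], kind="mergesort"
    )
    table["rank"] = np.arange(1, len(table) + 1)
    if n_select > len(table):
        warnings.warn(
            f"n_select={n_select} exceeds the {len(table)} compounds; selecting all",
            stacklevel=2,
        )
    table["selected"] = table["rank"] <= n_select
    return table.reset_index(drop=True)


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    ic50: float | None
    hill: float
    residual_sse: float
    converged: bool
    note: str = ""


def _4pl(u: np.ndarray, bottom: float, span: float, u50: float, hill: float) -> np.ndarray:
    return bottom + span / (1.0 + np.exp(hill * (u - u50)))


class FourParamLogistic(RegressorMixin, BaseEstimator):
    """Four-parameter logistic dose-response model fit on log-dose.

    ``y = bottom + (top - bottom) / (1 + exp(hill * (ln d - ln IC50)))``
    with ``top - bottom >= 0`` enforced by the span parameterization (the
    Hill slope carries the orientation).  Fitting is least squares with
    multi-start initialization from the data quantiles.  Zero doses are
    mapped to ``zero_dose_fraction`` times the smallest positive dose.

    Fitted attributes: ``bottom_``, ``top_``, ``ic50_`` (None when the fit
    is degenerate), ``hill_``, ``residual_sse_``, ``converged_``.
    """

    def __init__(
        self,
        zero_dose_fraction: float = 0.01,
        flat_tol: float = 1e-3,
        max_nfev: int = 2000,
    ) -> None:
        self.zero_dose_fraction = zero_dose_fraction
        self.flat_tol = flat_tol
        self.max_nfev = max_nfev

    def fit(self, doses, responses) -> "FourParamLogistic":
        d = np.asarray(doses, dtype=float).ravel()
        y = np.asarray(responses, dtype=float).ravel()
        if d.shape != y.shape:
            raise ValueError("doses and responses must have the same length")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite responses")
        if np.any(d < 0):
            raise ValueError("doses must be >= 0")
        if len(np.unique(d)) < 4:
            raise ValueError("need >= 4 distinct doses for a 4-parameter fit")
        pos = d[d > 0]
        if pos.size == 0:
            raise ValueError("need at least one positive dose")
        d = np.where(d == 0, self.zero_dose_fraction * pos.min(), d)
        u = np.log(d)

        scale = max(float(np.ptp(y)), 1e-12)
        self.converged_ = False
        self.note_ = ""
        if np.ptp(y) < self.flat_tol * max(abs(float(np.mean(y))), 1.0):
            # flat data: no dose dependence resolvable
            self.bottom_ = float(np.mean(y))
            self.top_ = float(np.mean(y))
            self.ic50_ = None
            self.hill_ = 0.0
            self.residual_sse_ = float(((y - np.mean(y)) ** 2).sum())
            self.note_ = "flat responses; degenerate fit"
            return self

        def resid(theta):
            bottom, span, u50, hill = theta
            return _4pl(u, bottom, span, u50, hill) - y

        ymin, ymax = float(y.min()), float(y.max())
        lb = [ymin - 2 * scale, 0.0, u.min() - 5.0, -20.0]
        ub = [ymax + 2 * scale, 4 * scale, u.max() + 5.0, 20.0]
        best = None
        for u50_init in np.quantile(u, [0.25, 0.5, 0.75]):
            for hill_init in (-2.0, -1.0, 1.0, 2.0):
                theta0 = [ymin, ymax - ymin, float(u50_init), hill_init]
                try:
                    res = least_squares(
                        resid, theta0, bounds=(lb, ub), max_nfev=self.max_nfev
                    )
                except Exception:
                    continue
                sse = float(np.sum(res.fun**2))
                if best is None or sse < best[0]:
                    best = (sse, res)
        if best is None:
            raise RuntimeError("4PL optimization failed from every start")
        sse, res = best
        bottom, span, u50, hill = res.x
        self.bottom_ = float(bottom)
        self.top_ = float(bottom + span)
        self.hill_ = float(hill)
        self.residual_sse_ = sse
        if span < self.flat_tol * scale or abs(hill) < 1e-6:
            self.ic50_ = None
            self.note_ = "span or slope collapsed; IC50 not identifiable"
        else:
            self.ic50_ = float(np.exp(u50))
            self.converged_ = bool(res.success)
        return self

    def predict(self, doses) -> np.ndarray:
        check_is_fitted(self, "bottom_")
        d = np.asarray(doses, dtype=float).ravel()
        d = np.where(d <= 0, np.min(d[d > 0]) * self.zero_dose_fraction if (d > 0).any() else 1e-9, d)
        if self.ic50_ is None:
            return np.full_like(d, self.bottom_, dtype=float)
        return _4pl(np.log(d), self.bottom_, self.top_ - self.bottom_, np.log(self.ic50_), self.hill_)


def fit_dose_response(doses, responses, config: dict | None = None) -> DoseResponseFit:
    """Functional wrapper over :class:`FourParamLogistic`."""
    est = FourParamLogistic(**(config or {})).fit(doses, responses)
    return DoseResponseFit(
        bottom=est.bottom_,
        top=est.top_,
        ic50=est.ic50_,
        hill=est.hill_,
        residual_sse=est.residual_sse_,
        converged=est.converged_,
        note=est.note_,
    )


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of two samples.

    ``u`` is the U statistic of ``x`` (number of pairs with x > y plus half
    the ties), so identical samples give ``u = n1*n2/2`` and all-x-below-y
    gives ``u = 0``.
    """

    u: float
    p_value: float
    n1: int
    n2: int
    direction: str  # "x<y" | "x>y" | "x~y"
    method: str  # "exact" | "normal"


#: enumeration cap for the exact two-sided p-value (number of group-label
#: assignments actually enumerated)
_EXACT_MAX_COMB = 500_000


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test with midranks for ties.

    The p-value is exact (full enumeration of group-label assignments,
    valid under ties) for small samples — ``n1*n2 <= 400`` and a feasible
    enumeration count — and otherwise uses the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u = float(r1 - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0
    if u > mu:
        direction = "x>y"
    elif u < mu:
        direction = "x<y"
    else:
        direction = "x~y"

    n_comb = math.comb(n1 + n2, n1)
    if n1 * n2 <= 400 and n_comb <= _EXACT_MAX_COMB:
        # exhaustive enumeration of which pooled ranks belong to group 1;
        # symmetric two-sided tail |U - mu| >= |u_obs - mu|
        obs_dev = abs(u - mu) - 1e-9
        hits = 0
        idx_all = range(n1 + n2)
        for combo in itertools.combinations(idx_all, n1):
            u_c = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u_c - mu) >= obs_dev:
                hits += 1
        p = hits / n_comb
        method = "exact"
    else:
        n = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / np.sqrt(var)
            p = float(min(2.0 * norm.sf(max(z, 0.0)), 1.0))
        method = "normal"
    return GroupComparison(
        u=u, p_value=float(min(p, 1.0)), n1=n1, n2=n2,
        direction=direction, method=method,
    )


#: fixed RPS histogram binning of the QC tables (percent-of-median units)
QC_BIN_WIDTH = 10.0


def screen_qc(
    results: pd.DataFrame,
    well_table: pd.DataFrame,
    readout_col: str = "rps",
) -> dict:
    """Screen-level QC tables.

    ``results`` is the :func:`aggregate_and_rank` output; ``well_table``
    holds one row per well with a ``role`` column and a per-well normalized
    readout.  Returns the empirical cumulative distribution of mean RPS,
    fixed-bin histograms of the control vs selected-compound wells, and
    their Mann-Whitney comparison.
    """
    mean_rps = np.sort(results["mean_rps"].dropna().to_numpy())
    ecdf = pd.DataFrame(
        {
            "mean_rps": mean_rps,
            "ecdf": np.arange(1, len(mean_rps) + 1) / max(len(mean_rps), 1),
        }
    )
    selected = set(results.loc[results["selected"], "compound_id"])
    ctrl = well_table.loc[well_table["role"] == "control", readout_col].dropna().to_numpy()
    hit = (
        well_table.loc[
            (well_table["role"] == "compound")
            & (well_table["compound_id"].isin(selected)),
            readout_col,
        ]
        .dropna()
        .to_numpy()
    )
    values = np.concatenate([ctrl, hit]) if (len(ctrl) or len(hit)) else np.array([0.0])
    top = max(float(values.max()), QC_BIN_WIDTH) if len(values) else QC_BIN_WIDTH
    edges = np.arange(0.0, np.ceil(top / QC_BIN_WIDTH) * QC_BIN_WIDTH + QC_BIN_WIDTH, QC_BIN_WIDTH)
    hist_rows = []
    for name, vals in (("control", ctrl), ("selected", hit)):
        counts, _ = np.histogram(vals, bins=edges)
        for lo, hi, c in zip(edges[:-1], edges[1:], counts):
            hist_rows.append({"group": name, "bin_low": lo, "bin_high": hi, "count": int(c)})
    hist = pd.DataFrame(hist_rows, columns=["group", "bin_low", "bin_high", "count"])
    comparison = (
        mann_whitney_u(ctrl, hit) if len(ctrl) and len(hit) else None
    )
    return {"ecdf": ecdf, "histograms": hist, "control_vs_selected": comparison}
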
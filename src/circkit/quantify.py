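"""Tier filtering, RPM normalization and differential circRNA abundance.

The three confidence tiers on BSJ read support are independent predicates
evaluated per circRNA over the samples of the analysed set:

* tier 1 — at least two junction reads in at least one sample;
* tier 2 — present (count >= presence threshold, default 1) in at least two
  samples AND a total of at least five reads across all samples (the
  alternative per-sample rule, >= 5 reads in >= 2 samples, is available via
  ``tier2_rule="per_sample"``);
* tier 3 — present in all samples or in all but one, regardless of read
  number (an all-zero circRNA is never "present").

Expression is quantified as reads per million mappable reads (RPM); the
differential test is a two-tailed two-sample t-test on RPM values (Welch by
default, pooled-variance Student optional) with a pseudocount-protected
log2 fold change.  A circRNA is called up (down) when log2FC >= 1 (<= -1)
and p < 0.05; both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CircRecord


@dataclass
class CountMatrix:
    """circRNAs x samples junction counts plus per-sample library sizes.

    ``linear`` optionally carries the parallel non-junction (linear host)
    counts on the same index/columns.
    """

    counts: pd.DataFrame
    mappable_reads: pd.Series
    linear: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.mappable_reads = self.mappable_reads.reindex(self.counts.columns)
        if self.mappable_reads.isna().any():
            missing = self.mappable_reads[self.mappable_reads.isna()].index.tolist()
            raise ValueError(f"no mappable_reads for sample(s) {missing}")
        if (self.mappable_reads <= 0).any():
            raise ValueError("mappable_reads must be positive for every sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @classmethod
    def from_records(
        cls,
        records_by_sample: Mapping[str, Sequence[CircRecord]],
        sample_sheet: pd.DataFrame,
    ) -> "CountMatrix":
        """Pivot per-sample call records into junction and linear matrices.

        Rows are keyed by ``chrom:start|end``; a circRNA absent from a
        sample's table gets a zero.
        """
        sheet = sample_sheet.set_index("sample_id")
        j: dict[str, dict[str, int]] = {}
        nj: dict[str, dict[str, int]] = {}
        for sid, records in records_by_sample.items():
            for r in records:
                j.setdefault(r.key, {})[sid] = r.junction_reads
                nj.setdefault(r.key, {})[sid] = r.non_junction_reads
        sample_ids = list(records_by_sample)
        keys = sorted(j)
        counts = pd.DataFrame(
            [[j[k].get(s, 0) for s in sample_ids] for k in keys],
            index=pd.Index(keys, name="circ_id"),
            columns=sample_ids,
        )
        linear = pd.DataFrame(
            [[nj[k].get(s, 0) for s in sample_ids] for k in keys],
            index=counts.index,
            columns=sample_ids,
        )
        return cls(counts, sheet["mappable_reads"].astype(float), linear)


def apply_tier_filters(
    matrix: CountMatrix | pd.DataFrame,
    presence_threshold: int = 1,
    tier2_rule: str = "methods",
) -> pd.DataFrame:
    """Evaluate the three tier predicates; returns a boolean frame.

    The tiers are deliberately independent (not nested): tier 3 asks for
    presence regardless of read number, so a tier-3 circRNA can fail tier 1.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else matrix
    if counts.shape[1] == 0:
        raise ValueError("tier filters need at least one sample")
    x = counts.to_numpy()
    n = x.shape[1]
    present = (x >= presence_threshold).sum(axis=1)
    tier1 = x.max(axis=1) >= 2 if len(x) else np.array([], dtype=bool)
    if tier2_rule == "methods":
        tier2 = (present >= 2) & (x.sum(axis=1) >= 5)
    elif tier2_rule == "per_sample":
        tier2 = (x >= 5).sum(axis=1) >= 2
    else:
        raise ValueError(f"unknown tier2_rule {tier2_rule!r}")
    tier3 = present >= max(1, n - 1)
    return pd.DataFrame(
        {"tier1": tier1, "tier2": tier2, "tier3": tier3}, index=counts.index
    )


def rpm_normalize(matrix: CountMatrix, which: str = "junction") -> pd.DataFrame:
    """counts x 1e6 / mappable_reads, per cell."""
    src = matrix.counts if which == "junction" else matrix.linear
    if src is None:
        raise ValueError("no linear counts in this matrix")
    return src * 1e6 / matrix.mappable_reads


def differential_abundance(
    rpm: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    epsilon: float = 0.01,
    test: str = "welch",
    log_transform: bool = False,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-circRNA group means, log2FC, t-test p-value and direction call.

    log2FC = log2((mean_case + eps) / (mean_control + eps)); the test runs
    on untransformed RPM unless ``log_transform`` (log2(RPM + eps)).  No
    multiple-testing correction is applied by default (raw p-values with an
    FC threshold); ``bh_correct`` adds a Benjamini-Hochberg q-value column.
    """
    sheet = sample_sheet.set_index("sample_id")
    case = [s for s in rpm.columns if sheet.at[s, "group"] == "case"]
    ctrl = [s for s in rpm.columns if sheet.at[s, "group"] == "control"]
    for name, cols in (("case", case), ("control", ctrl)):
        if len(cols) < 2:
            raise ValueError(f"group {name!r} has {len(cols)} sample(s); need >= 2")
    a = rpm[case].to_numpy(dtype=float)
    b = rpm[ctrl].to_numpy(dtype=float)
    mean_case = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    log2fc = np.log2((mean_case + epsilon) / (mean_ctrl + epsilon))
    ta, tb = (np.log2(a + epsilon), np.log2(b + epsilon)) if log_transform else (a, b)
    res = stats.ttest_ind(ta, tb, axis=1, equal_var=(test == "student"))
    p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: equal means -> no evidence (p = 1),
    # different means -> arbitrarily strong evidence (p = 0)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(ta.mean(axis=1), tb.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = 0.0
        log2fc = np.where(degenerate & same, 0.0, log2fc)
    out = pd.DataFrame(
        {
            "mean_rpm_case": mean_case,
            "mean_rpm_control": mean_ctrl,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=rpm.index,
    )
    p_eff = out["p_value"]
    if bh_correct:
        out["q_value"] = _benjamini_hochberg(out["p_value"].to_numpy())
        p_eff = out["q_value"]
    out["direction"] = np.select(
        [
            (out["log2fc"] >= lfc_threshold) & (p_eff < p_threshold),
            (out["log2fc"] <= -lfc_threshold) & (p_eff < p_threshold),
        ],
        ["up", "down"],
        default="none",
    )
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


@dataclass
class DirectionSummary:
    n_up: int
    n_down: int
    pct_up: float | None
    chi2: float | None = None
    chi2_p: float | None = None


def direction_summary(
    results: pd.DataFrame, other: pd.DataFrame | None = None
) -> DirectionSummary:
    """Up/down counts and percentage among significant circRNAs.

    With a second result set, a Pearson chi-squared test (no continuity
    correction) compares the two up/down splits; alone, a goodness-of-fit
    test against 50:50 is reported.  With zero significant circRNAs the
    percentage is undefined and no test is run.
    """
    n_up = int((results["direction"] == "up").sum())
    n_down = int((results["direction"] == "down").sum())
    if n_up + n_down == 0:
        return DirectionSummary(0, 0, None)
    pct_up = 100.0 * n_up / (n_up + n_down)
    if other is None:
        chi2, p = stats.chisquare([n_up, n_down])
        return DirectionSummary(n_up, n_down, pct_up, float(chi2), float(p))
    o_up = int((other["direction"] == "up").sum())
    o_down = int((other["direction"] == "down").sum())
    table = np.array([[n_up, n_down], [o_up, o_down]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return DirectionSummary(n_up, n_down, pct_up)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return DirectionSummary(n_up, n_down, pct_up, float(chi2), float(p))


@dataclass
class CorrelationResult:
    r2: float | None
    slope: float | None
    ok: bool


def circ_linear_correlation(
    circ_rpm: Sequence[float], linear_rpm: Sequence[float]
) -> CorrelationResult:
    """Squared Pearson correlation (and OLS slope) of paired mean RPMs."""
    x = np.asarray(circ_rpm, dtype=float)
    y = np.asarray(linear_rpm, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(None, None, False)
    lr = stats.linregress(x, y)
    return CorrelationResult(float(lr.rvalue**2), float(lr.slope), True)
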
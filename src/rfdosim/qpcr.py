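"""Relative qPCR expression and hormetic dose-response classification.

The pipeline starts from a table of cycle-threshold (Ct) values — one
row per (gene, condition, replicate) — and applies the standard Livak
2^(-ddCt) relative quantification against a single reference gene and a
sham/control condition:

    dCt  = Ct_target - Ct_reference          (per replicate)
    ddCt = dCt - mean(dCt_control)           (per replicate)
    RQ   = 2 ** (-ddCt)                      (per replicate)

Replicate-level relative quantities feed a one-way ANOVA across
conditions followed by Tukey's HSD, with each exposure condition
compared only against the control group.  Normality is checked with
Shapiro-Wilk as an advisory (the analysis does not switch tests on a
failed check).  Finally each gene's ordered amplitude ladder of fold
changes is classified as flat, monotonic, biphasic (U-shaped /
inverted) or mixed — the hormesis readout: a biphasic profile means the
response is present at both amplitude extremes but absent in between.

Ct tables are plain pandas DataFrames with columns
``gene, condition, replicate, ct`` (and an optional ``batch``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

REQUIRED_COLUMNS = ("gene", "condition", "replicate", "ct")


def _validate_ct_table(table: pd.DataFrame, ref_gene: str,
                       control_condition: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    if not np.isfinite(table["ct"].to_numpy(dtype=float)).all():
        raise ValueError("Ct values must all be finite")
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent from table")
    if ref_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {ref_gene!r} absent from table")
    # the reference gene must be measured in every (condition, replicate) sample
    samples = set(map(tuple, table[["condition", "replicate"]].drop_duplicates()
                      .itertuples(index=False)))
    ref_samples = set(map(tuple, table.loc[table["gene"] == ref_gene,
                                           ["condition", "replicate"]]
                          .itertuples(index=False)))
    gaps = sorted(samples - ref_samples)
    if gaps:
        raise ValueError(
            f"reference gene {ref_gene!r} missing for (condition, replicate) samples: {gaps}")


def replicate_quantities(table: pd.DataFrame, ref_gene: str,
                         control_condition: str) -> pd.DataFrame:
    """Per-replicate relative quantities 2**(-ddCt) for every target gene.

    Returns columns ``gene, condition, replicate, dct, rq`` (plus
    ``batch`` if present in the input).
    """
    _validate_ct_table(table, ref_gene, control_condition)
    keys = ["condition", "replicate"] + (["batch"] if "batch" in table.columns else [])
    ref = (table.loc[table["gene"] == ref_gene, keys + ["ct"]]
           .rename(columns={"ct": "ct_ref"}))
    targets = table.loc[table["gene"] != ref_gene]
    merged = targets.merge(ref, on=keys, how="left", validate="many_to_one")
    if merged["ct_ref"].isna().any():
        bad = merged.loc[merged["ct_ref"].isna(), keys].drop_duplicates()
        raise ValueError(f"no reference Ct for samples:\n{bad}")
    merged["dct"] = merged["ct"] - merged["ct_ref"]
    out = []
    for gene, grp in merged.groupby("gene", sort=False):
        ctrl_mean = grp.loc[grp["condition"] == control_condition, "dct"].mean()
        g = grp.copy()
        g["rq"] = 2.0 ** (-(g["dct"] - ctrl_mean))
        out.append(g)
    res = pd.concat(out, ignore_index=True)
    return res[["gene"] + keys + ["dct", "rq"]]


def relative_expression(table: pd.DataFrame, ref_gene: str,
                        control_condition: str) -> pd.DataFrame:
    """Fold change and SEM per (gene, condition).

    The fold change is 2**(-mean(ddCt)) — the mean taken on the cycle
    (log2) scale, equivalently the geometric mean of the per-replicate
    relative quantities — so the control condition's fold change is
    exactly 1 by construction of the mean.  SEM is the sample standard
    deviation of the per-replicate relative quantities over sqrt(n),
    matching the replicate-level scatter shown on expression bar plots.
    """
    rq = replicate_quantities(table, ref_gene, control_condition)
    rows = []
    for (gene, cond), grp in rq.groupby(["gene", "condition"], sort=False):
        vals = grp["rq"].to_numpy()
        n = len(vals)
        fold = 2.0 ** (np.log2(vals).mean())
        sem = vals.std(ddof=1) / math.sqrt(n) if n > 1 else np.nan
        rows.append((gene, cond, n, fold, sem))
    return pd.DataFrame(rows, columns=["gene", "condition", "n",
                                       "fold_change", "sem"])


def normality_check(values: Sequence[float]) -> Optional[float]:
    """Shapiro-Wilk p-value for one replicate set, or None if not computable.

    Advisory only: a low p flags non-normal replicates but does not
    switch the downstream ANOVA to a nonparametric test.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3 or len(vals) > 5000:
        return None
    if np.ptp(vals) == 0:
        return None  # zero variance: test undefined
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(vals).pvalue)


def anova_tukey(rq: pd.DataFrame, control_condition: str,
                log2_scale: bool = False) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD vs the control, per gene.

    Operates on replicate-level relative quantities (columns
    ``gene, condition, rq``), optionally log2-transformed.  Returns
    ``gene, condition, p_anova, p_adj`` with one row per non-control
    condition; ``p_adj`` is the Tukey-adjusted p of that condition
    against the control group.
    """
    rows = []
    for gene, grp in rq.groupby("gene", sort=False):
        vals = np.log2(grp["rq"].to_numpy()) if log2_scale else grp["rq"].to_numpy()
        conds = grp["condition"].to_numpy()
        uniq = pd.unique(conds)
        if control_condition not in uniq or len(uniq) < 2:
            raise ValueError(f"gene {gene!r}: need the control and >= 2 groups")
        groups = [vals[conds == c] for c in uniq]
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"gene {gene!r}: every condition needs >= 2 replicates")
        if all(np.ptp(g) == 0 for g in groups) and np.ptp(vals) == 0:
            # all observations identical: no evidence of any difference
            for c in uniq:
                if c != control_condition:
                    rows.append((gene, c, 1.0, 1.0))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_anova = float(stats.f_oneway(*groups).pvalue)
            tk = pairwise_tukeyhsd(vals, conds)
        res = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
        for _, r in res.iterrows():
            pair = {r["group1"], r["group2"]}
            if control_condition in pair:
                other = (pair - {control_condition}).pop()
                rows.append((gene, other, p_anova, float(r["p-adj"])))
    return pd.DataFrame(rows, columns=["gene", "condition", "p_anova", "p_adj"])


def significance_stars(p_adj: float) -> str:
    """Map an adjusted p-value to the conventional star label.

    Strict inequalities: <0.0001 '****', <0.001 '***', <0.01 '**',
    <0.05 '*', else 'ns'; boundary values get the weaker label.
    """
    if not (0.0 <= p_adj <= 1.0):
        raise ValueError(f"p-value must be in [0, 1], got {p_adj!r}")
    for thresh, label in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p_adj < thresh:
            return label
    return "ns"


def analyze(table: pd.DataFrame, ref_gene: str, control_condition: str,
            log2_scale: bool = False) -> pd.DataFrame:
    """Full expression analysis: fold changes, SEM, Tukey p, stars."""
    rq = replicate_quantities(table, ref_gene, control_condition)
    expr = relative_expression(table, ref_gene, control_condition)
    sig = anova_tukey(rq, control_condition, log2_scale=log2_scale)
    out = expr.merge(sig[["gene", "condition", "p_adj"]],
                     on=["gene", "condition"], how="left")
    out["stars"] = [significance_stars(p) if np.isfinite(p) else ""
                    for p in out["p_adj"].fillna(np.nan)]
    return out


# ---------------------------------------------------------------------------
# amplitude-ladder (hormesis) classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseProfile:
    """Ordered amplitude ladder of one gene's responses.

    ``amplitudes`` are the generator powers in dBm (control excluded),
    ordered strictly increasing; ``fold_changes`` and ``p_adj`` are the
    matching fold changes vs control and Tukey-adjusted p-values.
    """

    gene: str
    amplitudes: Tuple[float, ...]
    fold_changes: Tuple[float, ...]
    p_adj: Tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.amplitudes)
        if len(self.fold_changes) != n or len(self.p_adj) != n:
            raise ValueError("ladder arrays must have equal length")
        if any(b <= a for a, b in zip(self.amplitudes, self.amplitudes[1:])):
            raise ValueError("amplitudes must be strictly increasing")


def classify_dose_response(profile: DoseResponseProfile, alpha: float = 0.05,
                           spearman_threshold: float = 0.8) -> str:
    """Deterministic shape label for an amplitude-response ladder.

    Rules, in order, over the significance pattern (p_adj < alpha) along
    the increasing-amplitude ladder:

    * no significant condition -> ``flat``;
    * a contiguous significant run at each ladder end, separated by a
      non-significant interior, both runs responding in the same
      direction -> ``biphasic-U`` (up at the extremes) or
      ``biphasic-inverted`` (down);
    * >= 2 significant conditions whose fold changes are monotone in
      amplitude (Spearman |rho| >= threshold) -> ``monotonic-up`` /
      ``monotonic-down``;
    * anything else -> ``mixed``.

    This rule is an operationalization of the verbal "U-shaped /
    biphasic" description of hormetic dose-response curves; the alpha
    and Spearman thresholds are configuration, not biology.
    """
    n = len(profile.amplitudes)
    if n < 3:
        raise ValueError("need at least 3 non-control conditions to classify")
    sig = np.array([p < alpha for p in profile.p_adj])
    folds = np.asarray(profile.fold_changes, dtype=float)
    if not sig.any():
        return "flat"

    # terminal significant runs with a fully non-significant interior
    if sig[0] and sig[-1]:
        lo = 0
        while lo < n and sig[lo]:
            lo += 1
        hi = n - 1
        while hi >= 0 and sig[hi]:
            hi -= 1
        if lo <= hi and not sig[lo:hi + 1].any():
            low_run_up = bool(np.all(folds[:lo] > 1.0))
            low_run_down = bool(np.all(folds[:lo] < 1.0))
            high_run_up = bool(np.all(folds[hi + 1:] > 1.0))
            high_run_down = bool(np.all(folds[hi + 1:] < 1.0))
            if low_run_up and high_run_up:
                return "biphasic-U"
            if low_run_down and high_run_down:
                return "biphasic-inverted"

    idx = np.where(sig)[0]
    if len(idx) >= 2:
        rho = stats.spearmanr(np.asarray(profile.amplitudes)[idx], folds[idx]).statistic
        if np.isfinite(rho) and abs(rho) >= spearman_threshold:
            return "monotonic-up" if rho > 0 else "monotonic-down"
    return "mixed"


def amplitude_from_label(condition: str) -> float:
    """Parse a condition label like '+10dBm' / '-30 dBm' into dBm."""
    s = condition.strip().lower().replace("dbm", "").strip()
    return float(s)


def profile_from_results(results: pd.DataFrame, gene: str,
                         control_condition: str) -> DoseResponseProfile:
    """Build an ordered ladder from an ``analyze`` results table."""
    sub = results[(results["gene"] == gene)
                  & (results["condition"] != control_condition)].copy()
    if sub.empty:
        raise ValueError(f"no non-control rows for gene {gene!r}")
    sub["amplitude"] = sub["condition"].map(amplitude_from_label)
    sub = sub.sort_values("amplitude")
    return DoseResponseProfile(gene=gene,
                               amplitudes=tuple(sub["amplitude"]),
                               fold_changes=tuple(sub["fold_change"]),
                               p_adj=tuple(sub["p_adj"]))
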
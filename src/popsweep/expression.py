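"""Relative qPCR expression by the 2^-ddCt method with group statistics.

Each target gene's cycle threshold is normalized per sample against the
reference value of three housekeeping genes, then against a calibrator
group:

    dCt  = Ct_target - Ct_ref
    ddCt = dCt - mean(dCt over the calibrator group)
    RQ   = 2^-ddCt

The reference value is the arithmetic mean of the three housekeeping Cts,
which under the method's 100 %-efficiency assumption equals normalizing by
the geometric mean of the housekeeping expression levels.  Group summaries
report mean +/- SD, a one-way ANOVA, pairwise Welch t-tests and compact
letter displays at alpha = 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = ["ExpressionResult", "ddct", "group_summary"]


@dataclass
class ExpressionResult:
    """Per-sample relative quantities and the run's configuration."""

    per_sample: pd.DataFrame        # sample, group, gene, dct, ddct, rq
    housekeeping: tuple[str, ...]
    calibrator_group: str

    def gene(self, gene: str) -> pd.DataFrame:
        return self.per_sample[self.per_sample["gene"] == gene]


_REQUIRED = ["sample", "group", "gene", "rep", "ct"]


def ddct(table: pd.DataFrame, housekeeping: tuple[str, str, str],
         calibrator_group: str | None = None) -> ExpressionResult:
    """Compute dCt / ddCt / RQ from a long-format Ct table.

    ``table`` columns: sample, group, gene, rep, ct.  Technical replicates
    are averaged per (sample, gene) first.  The calibrator defaults to the
    alphabetically first group.  Every sample must have all three
    housekeeping genes.
    """
    missing_cols = [c for c in _REQUIRED if c not in table.columns]
    if missing_cols:
        raise ValueError(f"Ct table lacks columns {missing_cols}")
    if len(set(housekeeping)) != 3:
        raise ValueError("exactly three distinct housekeeping genes required")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")

    groups = sorted(table["group"].unique())
    if calibrator_group is None:
        calibrator_group = groups[0]
        logger.info("calibrator group defaulted to %r", calibrator_group)
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} not in table")

    # average technical replicates
    mean_ct = (table.groupby(["sample", "group", "gene"], sort=True)["ct"]
               .mean().reset_index())
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene",
                               values="ct")
    for hk in housekeeping:
        if hk not in wide.columns or wide[hk].isna().any():
            bad = wide.index[wide[hk].isna()].tolist() if hk in wide.columns \
                else wide.index.tolist()
            raise ValueError(f"housekeeping gene {hk!r} missing for {bad}")

    ref = wide[list(housekeeping)].mean(axis=1)
    targets = [g for g in wide.columns if g not in housekeeping]
    rows = []
    for gene in targets:
        dct = wide[gene] - ref
        calib = dct[dct.index.get_level_values("group") == calibrator_group]
        calib = calib.dropna()
        if calib.empty:
            raise ValueError(f"empty calibrator group for gene {gene!r}")
        ddct_vals = dct - calib.mean()
        for (sample, group), value in ddct_vals.items():
            if np.isnan(value):
                continue
            rows.append((sample, group, gene,
                         float(dct.loc[(sample, group)]), float(value),
                         float(2.0 ** -value)))
    per_sample = pd.DataFrame(
        rows, columns=["sample", "group", "gene", "dct", "ddct", "rq"])
    return ExpressionResult(per_sample, tuple(housekeeping), calibrator_group)


def _letters(groups: list[str], means: dict[str, float],
             sig: dict[tuple[str, str], bool]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb convention."""
    ordered = sorted(groups, key=lambda g: -means[g])
    classes: list[set[str]] = []
    for g in ordered:
        placed = False
        for cls in classes:
            if all(not sig[tuple(sorted((g, other)))] for other in cls):
                cls.add(g)
                placed = True
        if not placed:
            classes.append({g})
    # absorb classes fully contained in another
    classes = [c for i, c in enumerate(classes)
               if not any(c < other for j, other in enumerate(classes) if i != j)]
    letters = {g: "" for g in groups}
    for idx, cls in enumerate(classes):
        for g in cls:
            letters[g] += chr(ord("a") + idx)
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def group_summary(result: ExpressionResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene, per-group mean +/- SD with ANOVA and Welch pairwise tests.

    Returns one row per (gene, group) with columns mean, sd, n, letter,
    anova_f, anova_p.  Groups with a single sample are excluded from the
    tests with a warning.  Pairwise Welch p-values drive the letters.
    """
    out = []
    for gene, sub in result.per_sample.groupby("gene"):
        by_group = {g: s["rq"].to_numpy() for g, s in sub.groupby("group")}
        usable = {g: v for g, v in by_group.items() if len(v) >= 2}
        dropped = sorted(set(by_group) - set(usable))
        if dropped:
            logger.warning("gene %s: singleton groups %s excluded from tests",
                           gene, dropped)
        if len(usable) >= 2:
            f_stat, p_val = sps.f_oneway(*usable.values())
            sig = {}
            for g1, g2 in combinations(sorted(usable), 2):
                _, p = sps.ttest_ind(usable[g1], usable[g2], equal_var=False)
                sig[(g1, g2)] = bool(p < alpha)
            means = {g: float(v.mean()) for g, v in usable.items()}
            letters = _letters(sorted(usable), means, sig)
        else:
            f_stat = p_val = np.nan
            letters = {}
        for group, values in sorted(by_group.items()):
            out.append({
                "gene": gene, "group": group,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else np.nan,
                "n": len(values),
                "letter": letters.get(group, ""),
                "anova_f": float(f_stat), "anova_p": float(p_val),
            })
    return pd.DataFrame(out)
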
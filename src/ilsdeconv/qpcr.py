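"""Relative qPCR expression by the 2^-ddCt method.

Technical Ct triplicates are averaged per biological replicate; per
replicate dCt = Ct(target) - Ct(reference); ddCt is the difference of
condition mean dCts (parasitized minus control), and the fold change is
2^-ddCt. Significance of the control-vs-parasitized comparison uses
Welch's two-sample t-test on the replicate dCt sets (a permutation test
is available), at alpha = 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

HIGH_SD_CYCLES = 0.5


class QpcrError(ValueError):
    pass


def technical_collapse(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (genotype, condition, biological replicate, gene).

    Adds the technical SD, a high-SD flag (> 0.5 cycles) and a
    low-replication flag (fewer than 3 technical replicates).
    """
    required = {
        "genotype", "condition", "biological_replicate", "gene",
        "technical_replicate", "Ct",
    }
    missing = required - set(table.columns)
    if missing:
        raise QpcrError(f"Ct table missing columns: {sorted(missing)}")
    if (table["Ct"] <= 0).any():
        raise QpcrError("Ct values must be positive")
    grouped = table.groupby(
        ["genotype", "condition", "biological_replicate", "gene"],
        as_index=False,
    ).agg(
        mean_ct=("Ct", "mean"),
        sd_ct=("Ct", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
        n_technical=("Ct", "size"),
    )
    grouped["high_sd"] = grouped["sd_ct"] > HIGH_SD_CYCLES
    grouped["low_replication"] = grouped["n_technical"] < 3
    return grouped


@dataclass
class DdctResult:
    gene: str
    genotype: str
    mean_dct_control: float
    mean_dct_treated: float
    ddct: float
    fold_change: float
    p_value: float
    significant: bool
    n_control: int
    n_treated: int

    def as_dict(self) -> Dict:
        return {
            "gene": self.gene,
            "genotype": self.genotype,
            "mean_dct_control": self.mean_dct_control,
            "mean_dct_parasitized": self.mean_dct_treated,
            "ddct": self.ddct,
            "fold_change": self.fold_change,
            "p_value": self.p_value,
            "significant": self.significant,
            "n_control": self.n_control,
            "n_parasitized": self.n_treated,
        }


def _replicate_dct(
    collapsed: pd.DataFrame,
    reference_gene: str,
    target_gene: str,
    genotype: str,
    condition: str,
) -> np.ndarray:
    sub = collapsed[
        (collapsed["genotype"] == genotype)
        & (collapsed["condition"] == condition)
    ]
    ref = sub[sub["gene"] == reference_gene].set_index("biological_replicate")
    tgt = sub[sub["gene"] == target_gene].set_index("biological_replicate")
    reps = tgt.index.intersection(ref.index)
    dropped = tgt.index.difference(ref.index)
    if len(dropped):
        warnings.warn(
            f"{genotype}/{condition}: replicates {list(dropped)} lack a "
            f"reference-gene Ct and were excluded"
        )
    return (
        tgt.loc[reps, "mean_ct"].to_numpy()
        - ref.loc[reps, "mean_ct"].to_numpy()
    )


def ddct(
    collapsed: pd.DataFrame,
    reference_gene: str,
    target_gene: str,
    genotype: str,
    alpha: float = 0.05,
    test: str = "welch",
    n_permutations: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> DdctResult:
    """ddCt fold change and significance for one gene in one genotype.

    ddCt = mean(dCt parasitized) - mean(dCt control); fold = 2^-ddCt.
    p-value from a two-sided Welch t-test on the two replicate dCt sets
    (or an exact/Monte-Carlo permutation test of the mean difference when
    test="permutation"). Conditions with < 2 replicates give fold but
    p = NaN.
    """
    d_ctrl = _replicate_dct(
        collapsed, reference_gene, target_gene, genotype, "control"
    )
    d_trt = _replicate_dct(
        collapsed, reference_gene, target_gene, genotype, "parasitized"
    )
    if d_ctrl.size == 0 or d_trt.size == 0:
        raise QpcrError(
            f"{genotype}/{target_gene}: both conditions must be present"
        )
    ddct_val = float(d_trt.mean() - d_ctrl.mean())
    fold = float(2.0 ** (-ddct_val))
    if d_ctrl.size < 2 or d_trt.size < 2:
        p = float("nan")
    elif test == "welch":
        if np.var(d_ctrl) == 0 and np.var(d_trt) == 0:
            p = 1.0 if ddct_val == 0 else 0.0
        else:
            p = float(stats.ttest_ind(d_trt, d_ctrl, equal_var=False).pvalue)
    elif test == "permutation":
        p = _permutation_p(d_ctrl, d_trt, n_permutations, rng)
    else:
        raise QpcrError(f"unknown test {test!r}")
    return DdctResult(
        gene=target_gene,
        genotype=genotype,
        mean_dct_control=float(d_ctrl.mean()),
        mean_dct_treated=float(d_trt.mean()),
        ddct=ddct_val,
        fold_change=fold,
        p_value=p,
        significant=bool(p < alpha) if np.isfinite(p) else False,
        n_control=int(d_ctrl.size),
        n_treated=int(d_trt.size),
    )


def _permutation_p(
    a: np.ndarray, b: np.ndarray, n_permutations: int,
    rng: Optional[np.random.Generator],
) -> float:
    observed = abs(b.mean() - a.mean())
    pooled = np.concatenate([a, b])
    n_a = a.size
    total = pooled.size
    all_splits = None
    from math import comb

    if comb(total, n_a) <= n_permutations:
        all_splits = itertools.combinations(range(total), n_a)
    count = 0
    n_done = 0
    if all_splits is not None:
        for split in all_splits:
            mask = np.zeros(total, dtype=bool)
            mask[list(split)] = True
            diff = abs(pooled[~mask].mean() - pooled[mask].mean())
            count += diff >= observed - 1e-12
            n_done += 1
    else:
        rng = rng or np.random.default_rng(0)
        for _ in range(n_permutations):
            perm = rng.permutation(total)
            diff = abs(
                pooled[perm[n_a:]].mean() - pooled[perm[:n_a]].mean()
            )
            count += diff >= observed - 1e-12
            n_done += 1
    return count / n_done


def summarize_panel(
    collapsed: pd.DataFrame,
    reference_gene: str,
    genes: Sequence[str],
    genotypes: Sequence[str],
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """ddCt panel across genes x genotypes (validation-panel layout).

    Missing gene/genotype combinations yield NA rows; other cells are
    unaffected. Suitable for grouped bar plots of fold change with
    significance flags.
    """
    rows = []
    for gene in genes:
        for genotype in genotypes:
            present = (
                (collapsed["gene"] == gene)
                & (collapsed["genotype"] == genotype)
            ).any()
            if not present:
                rows.append(
                    {
                        "gene": gene, "genotype": genotype,
                        "mean_dct_control": np.nan,
                        "mean_dct_parasitized": np.nan,
                        "ddct": np.nan, "fold_change": np.nan,
                        "p_value": np.nan, "significant": False,
                        "n_control": 0, "n_parasitized": 0,
                    }
                )
                continue
            res = ddct(
                collapsed, reference_gene, gene, genotype,
                alpha=alpha, test=test,
            )
            rows.append(res.as_dict())
    return pd.DataFrame(rows)
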
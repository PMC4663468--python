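"""Expression normalisation and paralog expression-divergence tests.

:func:`normalize_expression` (log2(x+1), per-gene median centring) produces
the heat-map-ready matrix. The divergence test itself runs on the log2
scale *without* centring: the per-gene centring constant is estimated from
the data, so subtracting it would inject a shared noise shift into every
tissue's comparison and inflate the type-I error above its nominal level.

Divergence between a paralog pair is a per-tissue two-sample Student's
t-test (pooled variance by default; at 2-3 replicates per tissue the pooled
form holds its nominal level exactly under normality, while the Welch form
— available via ``equal_var=False`` — is conservative). A pair is divergent
when any tissue differs at P < alpha (0.05). No multiple-testing correction
is applied across tissues by default, matching the analysis this
reproduces; Benjamini–Hochberg is available behind a flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import ExpressionMatrix

logger = logging.getLogger("genefam")


@dataclass
class DivergenceResult:
    gene_a: str
    gene_b: str
    per_tissue: pd.DataFrame          # tissue, mean_diff, t_stat, p_value
    divergent_tissues: set[str] = field(default_factory=set)
    alpha: float = 0.05

    @property
    def is_divergent(self) -> bool:
        return len(self.divergent_tissues) >= 1


def normalize_expression(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) then per-gene (row) median centring."""
    if (values.values < 0).any():
        raise ValueError("expression values must be non-negative")
    logged = np.log2(values + 1.0)
    centred = logged.sub(logged.median(axis=1), axis=0)
    return centred


def paralog_divergence_test(
    gene_a: str,
    gene_b: str,
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> DivergenceResult:
    """Per-tissue t-tests between two paralogs on normalised expression.

    Tissues with fewer than 2 replicates are skipped with a warning.
    ``equal_var=False`` selects the Welch (unequal-variance) form;
    ``bh_correct`` applies Benjamini–Hochberg across tissues before calling
    divergence.
    """
    for g in (gene_a, gene_b):
        if g not in matrix.values.index:
            raise KeyError(f"gene {g} absent from expression matrix")
    # log scale, no per-gene centring (see module docstring)
    norm = np.log2(matrix.values.loc[[gene_a, gene_b]] + 1.0)
    rows = []
    for tissue in matrix.tissues():
        samples = matrix.samples_for(tissue)
        if len(samples) < 2:
            logger.warning("tissue %s has < 2 replicates; skipped", tissue)
            continue
        xa = norm.loc[gene_a, samples].to_numpy(dtype=float)
        xb = norm.loc[gene_b, samples].to_numpy(dtype=float)
        if np.allclose(xa, xb):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            if math.isnan(p):
                t, p = 0.0, 1.0
        rows.append({"tissue": tissue, "mean_diff": float(xa.mean() - xb.mean()),
                     "t_stat": float(t), "p_value": float(p)})
    per_tissue = pd.DataFrame(rows, columns=["tissue", "mean_diff", "t_stat", "p_value"])
    pvals = per_tissue["p_value"].to_numpy()
    if bh_correct and len(pvals):
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, pvals[i] * m / (rank_pos + 1))
            adj[i] = prev
        effective = adj
    else:
        effective = pvals
    divergent = {per_tissue["tissue"].iloc[i] for i in range(len(pvals))
                 if effective[i] < alpha}
    return DivergenceResult(gene_a=gene_a, gene_b=gene_b, per_tissue=per_tissue,
                            divergent_tissues=divergent, alpha=alpha)
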
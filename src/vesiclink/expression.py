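"""Expressed-gene calling from single-cell and bulk transcriptomics.

A gene is declared *not expressed* in a cell population when its log2 mean
expression falls more than ``|z_cutoff|`` standard deviations below the mean
of the population's (nonzero-mean) genes — the Hart-style one-shot z-test.
Genes with zero mean raw expression are always called not expressed and are
excluded from the mean/SD computation.

Boundary policy: equality at ``mean + z_cutoff * sd`` counts as expressed on
both the single-cell and the bulk route (the two source rules — "less than"
vs "above" — are contradictory exactly at the boundary; one consistent rule
is used and recorded in the context parameters).

The bulk route first normalizes raw counts with median-of-ratios size
factors, then applies the same z rule to per-group means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from vesiclink.errors import VesiclinkError
from vesiclink.io import ExpressionMatrix


@dataclass
class ExpressionContext:
    """Per-(cell type, condition) expression summary and expressed-gene calls."""

    cell_type: str
    condition: str
    mean_log2: pd.Series          # log2 mean expression; NaN for zero-mean genes
    expressed: pd.Series          # bool per gene
    z: pd.Series                  # z score; NaN for zero-mean genes
    params: dict = field(default_factory=dict)

    @property
    def expressed_genes(self) -> set:
        return set(self.expressed.index[self.expressed])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_log2": self.mean_log2,
            "z": self.z,
            "expressed": self.expressed,
        }).sort_index()

    def write_tsv(self, path) -> None:
        # %.17g round-trips doubles exactly: cached reloads must not lose
        # precision, or downstream deltas would drift between runs
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g",
                               index_label="gene")


def read_context_tsv(path, cell_type: str, condition: str) -> ExpressionContext:
    """Reload a context written by :meth:`ExpressionContext.write_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionContext(
        cell_type=cell_type, condition=condition,
        mean_log2=df["mean_log2"], z=df["z"],
        expressed=df["expressed"].astype(bool),
    )


def mean_by_group(matrix: ExpressionMatrix) -> dict:
    """Arithmetic mean raw expression per (cell type, condition) group.

    Zeros are included in the mean; cell order is irrelevant.
    """
    out: dict[tuple, pd.Series] = {}
    grouped = matrix.labels.groupby(["cell_type", "condition"], sort=True)
    for (ct, cond), sub in grouped:
        cells = sub.index
        if len(cells) == 0:
            raise VesiclinkError(f"empty group ({ct}, {cond})")
        out[(ct, cond)] = matrix.values[cells].mean(axis=1)
    if not out:
        raise VesiclinkError("no (cell_type, condition) groups in labels")
    return out


def call_expressed(mean_raw: Mapping | pd.Series, cell_type: str = "",
                   condition: str = "", z_cutoff: float = -3.0,
                   pseudocount: float = 0.0,
                   sd_mode: str = "population") -> ExpressionContext:
    """Apply the z-score expressed-gene rule to per-gene mean raw expression.

    Statistics (mean, SD of log2 values) are computed in a single pass over
    genes whose mean raw value (plus pseudocount) is positive. SD of zero
    (all equal) means every nonzero gene is expressed.
    """
    s = pd.Series(mean_raw, dtype=float)
    if (s < 0).any():
        raise VesiclinkError("negative mean expression values")
    shifted = s + pseudocount
    nonzero = shifted > 0
    if not nonzero.any():
        raise VesiclinkError("no expressed genes: all means are zero")

    x = pd.Series(np.nan, index=s.index)
    x[nonzero] = np.log2(shifted[nonzero])
    ddof = 0 if sd_mode == "population" else 1
    mu = float(x[nonzero].mean())
    sd = float(x[nonzero].std(ddof=ddof)) if nonzero.sum() > 1 else 0.0

    z = pd.Series(np.nan, index=s.index)
    expressed = pd.Series(False, index=s.index)
    if sd == 0.0:
        z[nonzero] = 0.0
        expressed[nonzero] = True
    else:
        z[nonzero] = (x[nonzero] - mu) / sd
        # boundary policy: equality at the cutoff counts as expressed
        expressed.loc[nonzero] = (z[nonzero] >= z_cutoff).to_numpy(dtype=bool)

    return ExpressionContext(
        cell_type=cell_type, condition=condition,
        mean_log2=x, expressed=expressed, z=z,
        params={"z_cutoff": z_cutoff, "pseudocount": pseudocount,
                "sd_mode": sd_mode, "boundary_policy": "ge"},
    )


def contexts_from_matrix(matrix: ExpressionMatrix, **call_kwargs) -> dict:
    """mean_by_group + call_expressed for every group; keyed (cell_type, condition)."""
    return {
        (ct, cond): call_expressed(means, cell_type=ct, condition=cond, **call_kwargs)
        for (ct, cond), means in mean_by_group(matrix).items()
    }


# ---------------------------------------------------------------------------
# bulk route
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples counts).

    Reference genes are those with nonzero counts in every sample; each
    sample's factor is the median over reference genes of
    ``count / geometric-mean-across-samples``.
    """
    if counts.shape[1] < 2:
        raise VesiclinkError("size factors need ≥2 samples")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise VesiclinkError("negative counts")
    reference = (arr > 0).all(axis=1)
    if not reference.any():
        raise VesiclinkError(
            "no gene has nonzero counts in all samples; consider a "
            "pseudo-reference fallback (config)"
        )
    log_counts = np.log(arr[reference])
    log_geo_mean = log_counts.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_counts - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns)


def normalize_bulk(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample by its median-of-ratios size factor."""
    return counts / size_factors(counts)


def restrict_shared_genes(*matrices: pd.DataFrame) -> list:
    """Restrict each matrix to the genes detected (present) in all of them."""
    shared = None
    for m in matrices:
        shared = set(m.index) if shared is None else shared & set(m.index)
    shared_sorted = sorted(shared or set())
    if not shared_sorted:
        raise VesiclinkError("no genes shared across the given datasets")
    return [m.loc[shared_sorted] for m in matrices]


def call_expressed_bulk(normalized: pd.DataFrame,
                        sample_groups: Mapping[str, tuple],
                        **call_kwargs) -> dict:
    """Per-sample-group expressed calls on mean normalized counts.

    *sample_groups* maps sample id -> (cell_type, condition). Returns a dict
    keyed by (cell_type, condition).
    """
    missing = set(normalized.columns) - set(sample_groups)
    if missing:
        raise VesiclinkError(f"samples without group labels: {sorted(missing)}")
    by_group: dict[tuple, list] = {}
    for sample, group in sample_groups.items():
        if sample in normalized.columns:
            by_group.setdefault(tuple(group), []).append(sample)
    return {
        group: call_expressed(normalized[samples].mean(axis=1),
                              cell_type=group[0], condition=group[1],
                              **call_kwargs)
        for group, samples in sorted(by_group.items())
    }
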
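"""Two-group differential expression of a single gene on log2 matrices.

Works on tab-delimited expression matrices in the style of GEO
series-matrix files (header row of sample identifiers, one row per
gene/probe).  The endpoint is the log2 fold change of one gene (IDO1 in
the motivating analyses) between a case and a control group, tested with
Welch's unequal-variance t; an alteration is called significant when the
fold change exceeds 2 (|log2FC| > 1) and p < 0.05.

The public comparisons this mirrors are the GEO accessions GSE10878
(Agilent-013282, 4 non-tumor vs 19 glioblastoma), GSE4290 (Affymetrix
HG-U133 Plus 2.0, 23 non-tumor vs 77 glioblastoma) and GSE31262 (ABI Human
Genome Survey v2, 5 neural stem cell vs 9 glioma stem cell samples); their
series-matrix files can be analyzed directly once downloaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_stats import GroupSample, welch_t

__all__ = [
    "ExpressionMatrix",
    "load_expression",
    "gene_log2fc",
    "flag_significant",
]

FOLD_CHANGE_THRESHOLD = 2.0  # |log2FC| > 1
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes × samples log2 expression values with two-group labels."""

    values: pd.DataFrame  # index: gene/probe ids; columns: sample ids
    groups: dict[str, str]  # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = {g for g in self.groups.values() if g not in ("case", "control")}
        if bad:
            raise ValueError(f"group labels must be 'case' or 'control', got {bad}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def swap_groups(self) -> "ExpressionMatrix":
        flipped = {
            s: ("case" if g == "control" else "control") for s, g in self.groups.items()
        }
        return ExpressionMatrix(self.values, flipped)


def load_expression(
    path: str | Path,
    label_map: dict[str, list[str]],
    apply_log2: bool = False,
) -> ExpressionMatrix:
    """Read a tab-delimited series-matrix-like expression file.

    The file must have a header row of sample identifiers and one row per
    gene/probe; metadata lines starting with ``!`` are skipped.
    ``label_map`` lists the sample ids of each group, e.g.
    ``{"case": [...], "control": [...]}``.  Values are assumed to be on the
    log2 scale already unless ``apply_log2`` is set.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="!")
    df.columns = [str(c).strip('"') for c in df.columns]
    df.index = [str(i).strip('"') for i in df.index]
    for gene, row in df.iterrows():
        for sample, v in row.items():
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric value {v!r} at gene {gene!r}, sample {sample!r}"
                ) from None
    df = df.astype(float)

    groups: dict[str, str] = {}
    for group in ("case", "control"):
        for sample in label_map.get(group, []):
            if sample not in df.columns:
                raise ValueError(f"{path}: sample {sample!r} not found in the matrix")
            groups[sample] = group
    df = df[[c for c in df.columns if c in groups]]
    if apply_log2:
        if (df.to_numpy() <= 0).any():
            raise ValueError("non-positive values cannot be log2-transformed")
        df = np.log2(df)
    return ExpressionMatrix(df, groups)


def gene_log2fc(
    m: ExpressionMatrix,
    gene: str,
    probes: list[str] | None = None,
    probe_rule: str = "max-mean",
) -> tuple[float, float]:
    """Log2 fold change (case − control) and Welch-t p-value for one gene.

    When several probe rows map to the gene (pass them via ``probes``),
    they are reduced to one expression profile first: ``max-mean`` keeps
    the probe with the highest mean expression, ``average`` averages the
    probes per sample.
    """
    rows = probes if probes is not None else [gene]
    missing = [r for r in rows if r not in m.values.index]
    if missing:
        raise KeyError(f"gene/probe rows not in matrix: {missing}")
    sub = m.values.loc[rows]
    if len(sub) > 1:
        if probe_rule == "max-mean":
            profile = sub.loc[sub.mean(axis=1).idxmax()]
        elif probe_rule == "average":
            profile = sub.mean(axis=0)
        else:
            raise ValueError(f"unknown probe rule {probe_rule!r}")
    else:
        profile = sub.iloc[0]

    case = GroupSample("case", profile[m.samples_in("case")].tolist())
    control = GroupSample("control", profile[m.samples_in("control")].tolist())
    if case.n < 2 or control.n < 2:
        raise ValueError("both groups need at least two samples")
    log2fc = float(np.mean(case.values) - np.mean(control.values))
    _, _, p = welch_t(case, control)
    return log2fc, p


def flag_significant(log2fc: float, p: float) -> bool:
    """Significant iff fold change > 2 (|log2FC| > 1) and p < 0.05."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    return abs(log2fc) > math.log2(FOLD_CHANGE_THRESHOLD) and p < P_THRESHOLD
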
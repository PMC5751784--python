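"""Count-table I/O and the synthetic fixture generator.

Count tables are tab-separated: a header row of sample ids, a first
column of gene ids, and non-negative integer counts. Gene ids are opaque
strings; no transcript-length or annotation columns are expected because
the method needs neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CountTableError, ParameterError
from .simulate import sample_observed_count

__all__ = ["CountMatrix", "read_counts", "write_counts", "make_fixture", "write_truth", "read_truth"]


@dataclass(frozen=True)
class CountMatrix:
    """A genes x samples table of non-negative integer counts."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountTableError(
                f"count matrix shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen = set()
            for i in ids:
                if i in seen:
                    raise CountTableError(f"duplicate {name} id {i!r}")
                seen.add(i)
        if counts.size and (
            not np.issubdtype(counts.dtype, np.integer) or np.any(counts < 0)
        ):
            raise CountTableError("counts must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            counts=df.to_numpy(),
        )


def read_counts(path: str | Path) -> CountMatrix:
    """Read and validate a tab-separated count table.

    Errors name the offending line (1-based, header is line 1), gene and
    sample where possible.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, index_col=0, header=0)
    except pd.errors.EmptyDataError:
        raise CountTableError(f"{path}: file is empty") from None
    except pd.errors.ParserError as exc:
        raise CountTableError(f"{path}: malformed table ({exc})") from None
    if df.shape[1] == 0:
        raise CountTableError(f"{path}: no sample columns found")

    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        # fast path: the whole table parses as integers
        values = df.to_numpy().astype(np.int64)
    except (TypeError, ValueError):
        values = _parse_cells(df, gene_ids, sample_ids, path)
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise CountTableError(
            f"{path}:{i + 2}: negative count {values[i, j]} for gene "
            f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=values)


def _parse_cells(df, gene_ids, sample_ids, path) -> np.ndarray:
    """Slow per-cell parse used only to localise a bad cell."""
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i, gid in enumerate(gene_ids):
        for j, sid in enumerate(sample_ids):
            cell = raw[i, j]
            line = i + 2  # header is line 1
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                raise CountTableError(
                    f"{path}:{line}: missing count for gene {gid!r}, sample "
                    f"{sid!r} (ragged row?)"
                )
            try:
                values[i, j] = int(str(cell).strip())
            except (TypeError, ValueError):
                raise CountTableError(
                    f"{path}:{line}: count {cell!r} for gene {gid!r}, sample "
                    f"{sid!r} is not an integer"
                ) from None
    return values


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a count table as TSV (inverse of :func:`read_counts`)."""
    cm.to_frame().to_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    """Read a truth table: columns gene_id, direction ('up'/'down')."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "direction"}
    if not required.issubset(df.columns):
        raise CountTableError(
            f"{path}: truth table must have columns {sorted(required)}"
        )
    return df


def make_fixture(
    n_genes: int,
    n_deg: int,
    fold: float,
    coverage_pair: Sequence[float],
    seed: int,
    population_N: int = 3_000_000,
    true_count_range: tuple[int, int] = (10, 10_000),
    sample_ids: tuple[str, str] = ("control", "treatment"),
) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a synthetic two-sample count table with known truth.

    True counts are drawn log-uniformly over ``true_count_range``. The
    first ``n_deg`` genes are differentially expressed: alternating up
    (treatment true count multiplied by ``fold``) and down (divided by
    ``fold``). Observed counts are drawn from the fragment-sampling
    mechanism at the given per-sample coverages. Fully seed-deterministic.

    Returns the count matrix and a truth frame with columns
    gene_id / direction / true_control / true_treatment.
    """
    if n_deg > n_genes:
        raise ParameterError(f"n_deg={n_deg} exceeds n_genes={n_genes}")
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if fold <= 1.0:
        raise ParameterError(f"fold must exceed 1, got {fold}")
    b0, b1 = coverage_pair
    lo, hi = true_count_range
    if not (1 <= lo < hi):
        raise ParameterError(f"invalid true count range {true_count_range}")
    if round(fold * hi) > population_N:
        raise ParameterError("fold x max true count exceeds the fragment population")

    rng = np.random.default_rng(seed)
    k_control = np.exp(
        rng.uniform(np.log(lo), np.log(hi), size=n_genes)
    ).round().astype(int)
    k_control = np.clip(k_control, 1, None)
    k_treatment = k_control.copy()
    directions = []
    for i in range(n_deg):
        if i % 2 == 0:
            k_treatment[i] = max(1, int(round(k_control[i] * fold)))
            directions.append("up")
        else:
            k_treatment[i] = max(1, int(round(k_control[i] / fold)))
            directions.append("down")

    S0 = int(round(b0 * population_N))
    S1 = int(round(b1 * population_N))
    x0 = sample_observed_count(k_control, S0, population_N, rng)
    x1 = sample_observed_count(k_treatment, S1, population_N, rng)

    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    cm = CountMatrix(
        gene_ids=gene_ids,
        sample_ids=list(sample_ids),
        counts=np.column_stack([x0, x1]),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids[:n_deg],
            "direction": directions,
            "true_control": k_control[:n_deg],
            "true_treatment": k_treatment[:n_deg],
        }
    )
    return cm, truth
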
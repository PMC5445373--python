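"""Data containers and TSV input/output for probe-level intensity tables.

The universal input is a tidy, long-format table of background-corrected,
quantile-normalized perfect-match probe intensities: one row per
(gene, probe set, probe, array) cell.  A probe set interrogates one exon,
so "probe set" and "exon" are used interchangeably downstream.  Model
fitting consumes one gene at a time as a dense arrays x probes matrix
(:class:`GeneTensor`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("reids")

REQUIRED_COLUMNS = ("gene_id", "probeset_id", "probe_id", "array_id", "intensity")

#: Significant digits used for all TSV output.
OUTPUT_SIG_DIGITS = 6
_FLOAT_FORMAT = "%.6g"


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class ProbeIntensityTable:
    """Validated long-format probe x array intensity table.

    Parameters
    ----------
    data
        DataFrame with columns gene_id, probeset_id, probe_id, array_id,
        intensity.
    is_log2
        Whether ``intensity`` is already on the log2 scale.  Linear-scale
        intensities must be strictly positive.
    """

    data: pd.DataFrame
    is_log2: bool

    def __post_init__(self) -> None:
        _validate_probe_table(self.data, self.is_log2)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.data["gene_id"].unique())

    @property
    def array_ids(self) -> list[str]:
        return sorted(self.data["array_id"].unique())

    @property
    def probeset_ids(self) -> list[str]:
        return sorted(self.data["probeset_id"].unique())

    def n_records(self) -> int:
        return len(self.data)


def _validate_probe_table(df: pd.DataFrame, is_log2: bool) -> None:
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataValidationError(f"missing required columns: {missing_cols}")
    if len(df) == 0:
        return
    if not np.isfinite(df["intensity"].to_numpy(dtype=float)).all():
        raise DataValidationError("non-finite intensity values present")
    if not is_log2 and (df["intensity"].to_numpy(dtype=float) <= 0).any():
        bad = df.loc[df["intensity"] <= 0].iloc[0]
        raise DataValidationError(
            "linear-scale intensities must be positive; first offender: "
            f"probe {bad['probe_id']!r} on array {bad['array_id']!r}"
        )

    probe_map = df.groupby("probe_id")["probeset_id"].nunique()
    multi = probe_map[probe_map > 1]
    if len(multi):
        raise DataValidationError(
            f"probe(s) mapped to more than one probe set: {sorted(multi.index[:5])}"
        )
    ps_map = df.groupby("probeset_id")["gene_id"].nunique()
    multi = ps_map[ps_map > 1]
    if len(multi):
        raise DataValidationError(
            f"probe set(s) mapped to more than one gene: {sorted(multi.index[:5])}"
        )

    dup = df.duplicated(subset=["probe_id", "array_id"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise DataValidationError(
            f"duplicate cell: probe {bad['probe_id']!r} on array {bad['array_id']!r}"
        )

    # Complete crossing of probes x arrays: the conditional updates assume
    # balanced, fully observed designs, so missing cells are a hard error.
    probes = df["probe_id"].unique()
    arrays = df["array_id"].unique()
    expected = len(probes) * len(arrays)
    if len(df) != expected:
        have = set(zip(df["probe_id"], df["array_id"]))
        missing = []
        for p in probes:
            for a in arrays:
                if (p, a) not in have:
                    missing.append((p, a))
                    if len(missing) >= 10:
                        break
            if len(missing) >= 10:
                break
        raise DataValidationError(
            f"missing cells (expected {expected} records, found {len(df)}); "
            f"first {len(missing)}: {missing}"
        )


def read_probe_table(path: str | Path, is_log2: bool = False) -> ProbeIntensityTable:
    """Read a tab-separated probe intensity table and validate it."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "gene_id": str,
            "probeset_id": str,
            "probe_id": str,
            "array_id": str,
        },
    )
    table = ProbeIntensityTable(df, is_log2=is_log2)
    logger.info(
        "read %d records: %d genes, %d probe sets, %d arrays from %s",
        table.n_records(),
        len(table.gene_ids),
        len(table.probeset_ids),
        len(table.array_ids),
        path,
    )
    return table


def write_probe_table(table: ProbeIntensityTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


@dataclass(frozen=True)
class ArrayMetadata:
    """Per-array experimental annotation: group label and optional pairing.

    ``pair_id`` supports paired designs (e.g. tumor/normal from the same
    patient); each pair id must occur exactly twice, once per group.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for c in ("array_id", "group"):
            if c not in df.columns:
                raise DataValidationError(f"array metadata missing column {c!r}")
        if df["array_id"].duplicated().any():
            raise DataValidationError("duplicate array_id in metadata")
        if "pair_id" in df.columns and df["pair_id"].notna().any():
            paired = df.loc[df["pair_id"].notna()]
            counts = paired.groupby("pair_id").agg(
                n=("array_id", "size"), g=("group", "nunique")
            )
            bad = counts[(counts["n"] != 2) | (counts["g"] != 2)]
            if len(bad):
                raise DataValidationError(
                    f"pair_id(s) not occurring exactly twice across both groups: "
                    f"{sorted(bad.index[:5])}"
                )

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def group_of(self) -> Mapping[str, str]:
        return dict(zip(self.data["array_id"], self.data["group"]))

    def validate_against(self, table: ProbeIntensityTable) -> None:
        meta_ids = set(self.data["array_id"])
        table_ids = set(table.array_ids)
        if meta_ids != table_ids:
            raise DataValidationError(
                f"array ids differ between metadata and intensity table: "
                f"only in metadata {sorted(meta_ids - table_ids)[:5]}, "
                f"only in table {sorted(table_ids - meta_ids)[:5]}"
            )


def read_array_metadata(path: str | Path) -> ArrayMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ArrayMetadata(df)


@dataclass(frozen=True)
class GeneTensor:
    """One gene's log2 intensities as a dense (arrays x probes) matrix.

    Probes are ordered lexicographically within lexicographically ordered
    probe sets; arrays are ordered lexicographically.  ``exon_of_probe``
    maps each probe column to its exon index k (0-based), ``n_per_exon``
    counts probes per exon, and ``z`` is the n x K exon-membership
    indicator (all ones for complete designs).
    """

    gene_id: str
    Y: np.ndarray  # (n_arrays, n_probes), log2 scale
    array_ids: tuple[str, ...]
    probe_ids: tuple[str, ...]
    probeset_ids: tuple[str, ...]
    exon_of_probe: np.ndarray  # (n_probes,) int
    z: np.ndarray = field(default=None)  # (n_arrays, n_exons)

    def __post_init__(self) -> None:
        if self.z is None:
            object.__setattr__(
                self, "z", np.ones((self.n_arrays, self.n_exons), dtype=float)
            )
        if self.Y.shape != (len(self.array_ids), len(self.probe_ids)):
            raise DataValidationError("Y shape inconsistent with axis labels")
        if not np.isfinite(self.Y).all():
            raise DataValidationError(f"non-finite Y for gene {self.gene_id}")
        if self.n_exons < 1 or self.n_arrays < 1:
            raise DataValidationError("gene tensor needs >= 1 exon and >= 1 array")
        if np.min(self.n_per_exon) < 1:
            raise DataValidationError("every exon needs >= 1 probe")

    @property
    def n_arrays(self) -> int:
        return self.Y.shape[0]

    @property
    def n_probes(self) -> int:
        return self.Y.shape[1]

    @property
    def n_exons(self) -> int:
        return len(self.probeset_ids)

    @property
    def n_per_exon(self) -> np.ndarray:
        return np.bincount(self.exon_of_probe, minlength=self.n_exons)

    def membership_matrix(self) -> np.ndarray:
        """(n_probes x n_exons) 0/1 matrix mapping probes to exons."""
        M = np.zeros((self.n_probes, self.n_exons))
        M[np.arange(self.n_probes), self.exon_of_probe] = 1.0
        return M


def build_gene_tensor(table: ProbeIntensityTable, gene_id: str) -> GeneTensor:
    """Extract one gene as a :class:`GeneTensor` (log2 scale).

    Linear-scale tables are log2-transformed here; log2 tables pass
    through verbatim.  Ordering is lexicographic on every axis so the
    result is invariant to input row order.
    """
    sub = table.data.loc[table.data["gene_id"] == gene_id]
    if len(sub) == 0:
        raise KeyError(f"gene {gene_id!r} not present in table")

    probe_info = (
        sub[["probeset_id", "probe_id"]]
        .drop_duplicates()
        .sort_values(["probeset_id", "probe_id"])
        .reset_index(drop=True)
    )
    probesets = tuple(probe_info["probeset_id"].unique())
    probe_ids = tuple(probe_info["probe_id"])
    exon_index = {ps: k for k, ps in enumerate(probesets)}
    exon_of_probe = np.array(
        [exon_index[ps] for ps in probe_info["probeset_id"]], dtype=int
    )

    wide = sub.pivot(index="array_id", columns="probe_id", values="intensity")
    wide = wide.sort_index().loc[:, list(probe_ids)]
    Y = wide.to_numpy(dtype=float)
    if not table.is_log2:
        Y = np.log2(Y)

    return GeneTensor(
        gene_id=gene_id,
        Y=Y,
        array_ids=tuple(wide.index),
        probe_ids=probe_ids,
        probeset_ids=probesets,
        exon_of_probe=exon_of_probe,
    )


def iter_gene_tensors(table: ProbeIntensityTable):
    """Yield :class:`GeneTensor` for every gene, in lexicographic order."""
    for gene_id in table.gene_ids:
        yield build_gene_tensor(table, gene_id)


EXON_SCORE_COLUMNS = (
    "gene_id",
    "probeset_id",
    "exon_score",
    "t_statistic",
    "p_value",
    "adjusted_p",
    "rank",
)


def write_results(
    exon_table: pd.DataFrame,
    array_scores: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the exon-score table and array-score matrix as TSV.

    ``exon_table`` columns follow :data:`EXON_SCORE_COLUMNS` (missing ones
    are emitted empty so headers are stable); ``array_scores`` is indexed
    by probeset_id with one column per array.  Values are written with 6
    significant digits; column order is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exon = exon_table.copy()
    for col in EXON_SCORE_COLUMNS:
        if col not in exon.columns:
            exon[col] = pd.Series(dtype=float)
    extra = [c for c in exon.columns if c not in EXON_SCORE_COLUMNS]
    exon = exon[list(EXON_SCORE_COLUMNS) + sorted(extra)]

    exon_path = out_dir / "exon_scores.tsv"
    exon.to_csv(exon_path, sep="\t", index=False, float_format=_FLOAT_FORMAT)

    scores_path = out_dir / "array_scores.tsv"
    arr = array_scores.copy()
    arr = arr.loc[sorted(arr.index), sorted(arr.columns)]
    arr.index.name = "probeset_id"
    arr.to_csv(scores_path, sep="\t", float_format=_FLOAT_FORMAT)

    logger.info(
        "wrote %d exon rows and %d x %d array-score matrix to %s",
        len(exon),
        arr.shape[0],
        arr.shape[1],
        out_dir,
    )
    return {"exon_scores": exon_path, "array_scores": scores_path}


def setup_logging(level: int = logging.INFO) -> None:
    """Configure structured logging of fit diagnostics to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(level)
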
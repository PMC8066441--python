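"""Count-table and metadata IO, validation, filtering, rarefaction.

The central container is :class:`CountTable`, a thin validated wrapper
around a pandas DataFrame with samples as rows and taxa as columns.
All downstream modules consume it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "SampleFrame",
    "DistanceMatrix",
    "ValidationError",
    "read_count_table",
    "read_metadata",
    "read_taxonomy",
    "filter_min_abundance",
    "rarefy",
    "rarefaction_curves",
    "aggregate_taxonomy",
    "split_habitats",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class CountTable:
    """Sample x taxon non-negative integer count matrix.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are samples, columns are taxa, entries non-negative integers.
    lineages : pandas.Series, optional
        Per-taxon semicolon-delimited ranked lineage (kingdom..species),
        indexed by taxon id.
    """

    counts: pd.DataFrame
    lineages: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValidationError("count table needs at least 1 sample and 1 taxon")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric entries in count table")
        if np.any(arr < 0):
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            r, c = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
            raise ValidationError(
                f"non-integer count at sample {df.index[r]!r}, taxon {df.columns[c]!r}"
            )
        self.counts = df.astype(np.int64)
        if self.lineages is not None:
            lin = self.lineages.reindex(df.columns)
            for tid, val in lin.dropna().items():
                if len(str(val).split(";")) > 7:
                    raise ValidationError(f"lineage of {tid!r} exceeds 7 ranks")
            self.lineages = lin

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def taxon_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def select_samples(self, ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(ids)].copy(), self.lineages)

    def to_tsv(self, path: str | Path, orientation: str = "samples_as_rows") -> None:
        df = self.counts if orientation == "samples_as_rows" else self.counts.T
        df.to_csv(path, sep="\t", index_label="id")


@dataclass
class SampleFrame:
    """Sample metadata: group labels, coordinates and environmental variables."""

    data: pd.DataFrame

    REQUIRED = ("group", "lat", "lon")

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        lat, lon = df["lat"].astype(float), df["lon"].astype(float)
        if ((lat < -90) | (lat > 90)).any():
            raise ValidationError("latitude outside [-90, 90]")
        if ((lon < -180) | (lon > 180)).any():
            raise ValidationError("longitude outside [-180, 180]")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def groups(self) -> pd.Series:
        return self.data["group"]

    def env_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def env(self) -> pd.DataFrame:
        return self.data[self.env_columns()].astype(float)

    def coords(self) -> pd.DataFrame:
        return self.data[["lat", "lon"]].astype(float)

    def check_matches(self, table: CountTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"samples absent from metadata: {sorted(missing)}")

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance (or similarity) matrix with labels."""

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal not exactly zero")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle, row-major (scipy ``squareform`` order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------------------
# readers


def read_count_table(
    path: str | Path,
    orientation: str = "auto",
    known_sample_ids: Iterable[str] | None = None,
    taxonomy: pd.Series | None = None,
) -> CountTable:
    """Read a TSV count table with either orientation.

    Parameters
    ----------
    orientation
        ``"samples_as_rows"``, ``"taxa_as_rows"`` or ``"auto"``.  Auto
        detection prefers the orientation whose row ids overlap
        ``known_sample_ids``; without that hint, the wider axis is taken
        to be the taxa (amplicon tables virtually always have far more
        taxa than samples).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".json":  # minimal BIOM-style JSON support
        return _read_biom_json(path, taxonomy)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    if orientation == "auto":
        if known_sample_ids is not None:
            known = set(map(str, known_sample_ids))
            rows_hit = len(known & set(df.index))
            cols_hit = len(known & set(df.columns))
            orientation = "samples_as_rows" if rows_hit >= cols_hit else "taxa_as_rows"
        else:
            orientation = "samples_as_rows" if df.shape[0] <= df.shape[1] else "taxa_as_rows"
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable(df, lineages=taxonomy)


def _read_biom_json(path: Path, taxonomy: pd.Series | None) -> CountTable:
    with open(path) as fh:
        doc = json.load(fh)
    taxa = [r["id"] for r in doc["rows"]]
    samples = [c["id"] for c in doc["columns"]]
    mat = np.zeros((len(taxa), len(samples)))
    if doc.get("matrix_type") == "sparse":
        for r, c, v in doc["data"]:
            mat[int(r), int(c)] = v
    else:
        mat = np.asarray(doc["data"], dtype=float)
    df = pd.DataFrame(mat.T, index=samples, columns=taxa)
    return CountTable(df, lineages=taxonomy)


def read_metadata(path: str | Path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleFrame(df)


def read_taxonomy(path: str | Path) -> pd.Series:
    """Read a two-column TSV of taxon id and semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    ser = df.iloc[:, 0].astype(str)
    ser.index = ser.index.astype(str)
    return ser


# ---------------------------------------------------------------------------
# operations


def filter_min_abundance(table: CountTable, min_total: int = 10) -> CountTable:
    """Drop taxa whose total count across all samples is below ``min_total``.

    The threshold is a strict "keep if total >= min_total" so that
    ``min_total=0`` is the identity.  Samples are retained even if they
    end up all-zero.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = table.taxon_totals() >= min_total
    kept = table.counts.loc[:, keep]
    lin = table.lineages.loc[kept.columns] if table.lineages is not None else None
    return CountTable(kept.copy(), lin)


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Uses a multivariate hypergeometric draw per sample, i.e. the
    distribution of picking ``depth`` reads uniformly at random from the
    sample's observed reads.
    """
    totals = table.sample_totals()
    shallow = totals[totals < depth]
    if len(shallow):
        raise ValueError(
            f"samples shallower than depth {depth}: "
            + ", ".join(f"{s} ({t})" for s, t in shallow.items())
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.matrix())
    for i, row in enumerate(table.matrix()):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    df = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CountTable(df, table.lineages)


def rarefaction_curves(
    table: CountTable,
    fractions: Sequence[float],
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+/- SE) richness per sample at a grid of subsampling fractions.

    Returns a long-format frame with columns ``sample_id``, ``fraction``,
    ``depth``, ``mean_richness``, ``se``.  Fraction 1.0 reproduces the
    observed richness with zero SE.
    """
    fractions = sorted(fractions)
    if not fractions or fractions[0] <= 0 or fractions[-1] > 1:
        raise ValueError("fractions must lie in (0, 1]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = totals[totals == 0].index.tolist()
        raise ValueError(f"all-zero samples: {empty}")
    rng = np.random.default_rng(seed)
    records = []
    for sid, row in table.counts.iterrows():
        counts = row.to_numpy()
        total = int(counts.sum())
        for frac in fractions:
            depth = max(1, int(round(frac * total)))
            if depth >= total:
                rich = np.full(reps, int((counts > 0).sum()))
            else:
                rich = np.empty(reps)
                for r in range(reps):
                    sub = rng.multivariate_hypergeometric(counts, depth)
                    rich[r] = int((sub > 0).sum())
            records.append(
                {
                    "sample_id": sid,
                    "fraction": frac,
                    "depth": depth,
                    "mean_richness": float(rich.mean()),
                    "se": float(rich.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
                }
            )
    return pd.DataFrame.from_records(records)


def aggregate_taxonomy(
    table: CountTable, rank: str, pooled_label: str = "__pooled__"
) -> pd.DataFrame:
    """Read fractions per sample (and pooled) at a taxonomic rank.

    Taxa with no lineage, or whose lineage does not reach ``rank``, are
    reported under ``"unclassified"``.  Each row sums to 1.
    """
    if table.lineages is None:
        raise ValueError("count table carries no lineages")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; choose from {RANKS}")
    level = RANKS.index(rank)
    labels = []
    for tid in table.taxon_ids:
        lin = table.lineages.get(tid)
        if lin is None or (isinstance(lin, float) and np.isnan(lin)):
            labels.append("unclassified")
            continue
        parts = [p.strip() for p in str(lin).split(";")]
        if level < len(parts) and parts[level]:
            labels.append(parts[level])
        else:
            labels.append("unclassified")
    grouped = table.counts.T.groupby(np.asarray(labels)).sum().T
    pooled = grouped.sum(axis=0).to_frame(pooled_label).T
    out = pd.concat([grouped, pooled])
    row_sums = out.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("cannot compute fractions for all-zero samples")
    return out.div(row_sums, axis=0)


def split_habitats(
    table: CountTable,
    frame: SampleFrame,
    group_map: Mapping[str, str] | None = None,
    exclusions: Sequence[str] = (),
) -> dict[str, CountTable]:
    """Partition samples into habitat groups, dropping excluded samples.

    ``group_map`` optionally merges metadata group labels into coarser
    habitat labels (e.g. tributary+river -> river).  All group tables
    share the full taxon axis.
    """
    frame.check_matches(table)
    unknown = [e for e in exclusions if e not in table.sample_ids]
    if unknown:
        raise ValueError(f"unknown exclusion ids: {unknown}")
    excl = set(exclusions)
    out: dict[str, list[str]] = {}
    for sid in table.sample_ids:
        if sid in excl:
            continue
        raw = str(frame.groups.loc[sid])
        label = group_map.get(raw, raw) if group_map else raw
        out.setdefault(label, []).append(sid)
    return {g: table.select_samples(ids) for g, ids in out.items()}
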
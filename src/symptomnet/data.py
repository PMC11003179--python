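"""Item-response containers and CSV/metadata input-output.

An analysis dataset is an ``n x p`` integer matrix of ordinal responses
(rows = respondents, columns = questionnaire items) plus per-item metadata:
the item label, its community (cluster) label used for bridge statistics,
and its number of response categories.  Missing responses are coded as
:data:`MISSING` (−1) internally and as empty cells on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError

#: Internal missing-value code (empty CSV cell on disk).
MISSING = -1


@dataclass(frozen=True)
class Item:
    """Metadata for one ordinal item.

    Parameters
    ----------
    label : str
        Column name, e.g. ``"PTS3"``.
    community : str
        Cluster label, e.g. ``"PTS"`` or ``"PTG"``.
    n_categories : int
        Number of ordered response categories; valid scores are
        ``0 .. n_categories - 1``.
    """

    label: str
    community: str
    n_categories: int

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValidationError(
                f"item {self.label!r}: n_categories must be >= 2, "
                f"got {self.n_categories}"
            )


@dataclass
class ItemResponseMatrix:
    """Ordinal responses plus item metadata.

    ``values`` is an ``(n, p)`` integer array; entry ``values[i, j]`` is in
    ``0 .. items[j].n_categories - 1`` or :data:`MISSING`.
    """

    values: np.ndarray
    items: list[Item] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValidationError("values must be an integer array")
        if self.values.shape[1] != len(self.items):
            raise ValidationError(
                f"{self.values.shape[1]} data columns but "
                f"{len(self.items)} item metadata entries"
            )
        for j, item in enumerate(self.items):
            col = self.values[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= item.n_categories))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"item {item.label!r}: value {col[i]} at row {i} outside "
                    f"0..{item.n_categories - 1}"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def labels(self) -> list[str]:
        return [it.label for it in self.items]

    @property
    def communities(self) -> list[str]:
        return [it.community for it in self.items]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.labels)
        return df.mask(df == MISSING)

    def subset(self, labels: list[str]) -> "ItemResponseMatrix":
        """Column subset by label (used e.g. for single-cluster networks)."""
        index = {it.label: j for j, it in enumerate(self.items)}
        missing = [lb for lb in labels if lb not in index]
        if missing:
            raise ValidationError(f"unknown item labels: {missing}")
        cols = [index[lb] for lb in labels]
        return ItemResponseMatrix(self.values[:, cols],
                                  [self.items[j] for j in cols])


def write_item_responses(data: ItemResponseMatrix, csv_path: str | Path,
                         meta_path: str | Path) -> None:
    """Write responses as CSV (header = item labels, empty cell = missing)
    and metadata as YAML."""
    df = pd.DataFrame(data.values.astype(object), columns=data.labels)
    df = df.mask(df == MISSING)
    df.to_csv(csv_path, index=False)
    write_metadata(data.items, meta_path)


def write_metadata(items: list[Item], meta_path: str | Path) -> None:
    meta = {
        "items": [
            {"label": it.label, "community": it.community,
             "n_categories": it.n_categories}
            for it in items
        ]
    }
    Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_metadata(meta_path: str | Path) -> list[Item]:
    try:
        raw = yaml.safe_load(Path(meta_path).read_text())
        entries = raw["items"]
    except (OSError, KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValidationError(f"cannot read item metadata {meta_path}: {exc}")
    return [Item(str(e["label"]), str(e["community"]), int(e["n_categories"]))
            for e in entries]


def validate_input(path: str | Path | io.IOBase,
                   items: list[Item]) -> ItemResponseMatrix:
    """Read and validate an item-response CSV against item metadata.

    Columns are matched to metadata by label (order on disk is free).  Every
    violation — unknown or absent columns, non-integer cells, out-of-range
    scores — is collected and reported with row/column coordinates in a
    single :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValidationError(f"cannot read input CSV: {exc}")
    if df.shape[0] == 0:
        raise ValidationError("input CSV contains no data rows")

    problems: list[str] = []
    by_label = {it.label: it for it in items}
    unknown = [c for c in df.columns if c not in by_label]
    absent = [lb for lb in by_label if lb not in df.columns]
    if unknown:
        problems.append(f"columns not in metadata: {unknown}")
    if absent:
        problems.append(f"metadata items absent from CSV: {absent}")
    if problems:
        raise ValidationError("; ".join(problems))

    n = df.shape[0]
    values = np.full((n, len(items)), MISSING, dtype=np.int64)
    for j, item in enumerate(items):
        col = df[item.label]
        for i, cell in enumerate(col):
            if pd.isna(cell):
                continue
            x = float(cell)
            if x != int(x):
                problems.append(
                    f"row {i}, item {item.label!r}: non-integer value {cell}")
                continue
            v = int(x)
            if not 0 <= v < item.n_categories:
                problems.append(
                    f"row {i}, item {item.label!r}: value {v} outside "
                    f"0..{item.n_categories - 1}")
                continue
            values[i, j] = v
    if problems:
        raise ValidationError("invalid input: " + "; ".join(problems))
    return ItemResponseMatrix(values, list(items))
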
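"""Omics matrix container plus TSV/CSV I/O.

Matrices are dense feature x sample grids with an explicit observation
mask; missing cells are carried as NaN in ``values`` and ``False`` in
``mask``.  All readers/writers round-trip (values, mask, ids) exactly.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_MISSING_TOKENS = frozenset({"NA", "", "NaN"})


class MatrixParseError(ValueError):
    """A cell could not be parsed as a number."""


class MatrixValidationError(ValueError):
    """The matrix violates a structural invariant."""


@dataclass
class OmicsMatrix:
    """A numeric M x N omics matrix (rows = features, columns = samples).

    Parameters
    ----------
    values
        Float array of shape (M, N).  Entries where ``mask`` is False are
        missing; their stored value is irrelevant (NaN by convention) and
        is never read by any computation in this package.
    mask
        Boolean array of shape (M, N); True marks an observed cell.
    feature_ids, sample_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    mask: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise MatrixValidationError(
                f"matrix must be at least 2x2, got {m}x{n}"
            )
        if self.mask.shape != self.values.shape:
            raise MatrixValidationError("mask shape does not match values")
        if len(self.feature_ids) != m:
            raise MatrixValidationError("feature_ids length != number of rows")
        if len(self.sample_ids) != n:
            raise MatrixValidationError("sample_ids length != number of columns")
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise MatrixValidationError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        if not np.all(np.isfinite(self.values[self.mask])):
            bad = np.argwhere(~np.isfinite(self.values) & self.mask)[0]
            raise MatrixValidationError(
                f"non-finite value in observed cell "
                f"({self.feature_ids[bad[0]]}, {self.sample_ids[bad[1]]})"
            )

    # -- basic geometry ---------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    def is_fully_observed(self) -> bool:
        return bool(self.mask.all())

    def observed_values(self) -> np.ndarray:
        """Values with missing cells replaced by 0 (safe for linear algebra)."""
        return np.where(self.mask, self.values, 0.0)

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.copy(), self.mask.copy(),
            list(self.feature_ids), list(self.sample_ids),
        )

    def transpose(self) -> "OmicsMatrix":
        return OmicsMatrix(
            self.values.T.copy(), self.mask.T.copy(),
            list(self.sample_ids), list(self.feature_ids),
        )


@dataclass
class LabelVector:
    """Categorical subgroup assignment for one matrix axis."""

    ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.labels):
            raise MatrixValidationError("ids and labels differ in length")
        self.labels = [str(l) for l in self.labels]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_classes(self) -> int:
        return len(set(self.labels))

    def as_codes(self) -> np.ndarray:
        """Integer codes in order of first appearance."""
        mapping: dict[str, int] = {}
        codes = []
        for l in self.labels:
            if l not in mapping:
                mapping[l] = len(mapping)
            codes.append(mapping[l])
        return np.asarray(codes, dtype=np.int64)


# -- readers / writers ----------------------------------------------------

def read_matrix(
    path,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    delimiter: str = "\t",
) -> OmicsMatrix:
    """Read a delimited matrix: first row = sample ids, first column = feature ids.

    Cells matching one of ``missing_tokens`` (after stripping surrounding
    whitespace) become missing; everything else must parse as a finite real.
    """
    missing_tokens = set(missing_tokens)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise MatrixParseError(f"{path}: empty file")
    sample_ids = [c.strip() for c in rows[0][1:]]
    feature_ids: list[str] = []
    values: list[list[float]] = []
    mask: list[list[bool]] = []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(sample_ids) + 1:
            raise MatrixParseError(
                f"{path}: line {r} has {len(row)} fields, expected {len(sample_ids) + 1}"
            )
        feature_ids.append(row[0].strip())
        vrow, mrow = [], []
        for c, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok in missing_tokens:
                vrow.append(math.nan)
                mrow.append(False)
                continue
            try:
                x = float(tok)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: cannot parse cell at row {row[0].strip()!r}, "
                    f"column {sample_ids[c]!r}: {cell!r}"
                ) from None
            if not math.isfinite(x):
                raise MatrixParseError(
                    f"{path}: non-finite value at row {row[0].strip()!r}, "
                    f"column {sample_ids[c]!r}: {cell!r}"
                )
            vrow.append(x)
            mrow.append(True)
        values.append(vrow)
        mask.append(mrow)
    return OmicsMatrix(np.asarray(values), np.asarray(mask), feature_ids, sample_ids)


def write_matrix(m: OmicsMatrix, path, delimiter: str = "\t"):
    """Write ``m`` as TSV with 'NA' in missing cells; lossless round-trip."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow([""] + list(m.sample_ids))
        for i, fid in enumerate(m.feature_ids):
            row = [fid]
            for j in range(m.n_samples):
                row.append(repr(float(m.values[i, j])) if m.mask[i, j] else "NA")
            w.writerow(row)
    return path


def read_labels(path, delimiter: str = "\t") -> LabelVector:
    """Read a two-column (id, label) file; a header line 'id<TAB>label' is skipped."""
    ids, labels = [], []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter=delimiter):
            if not row:
                continue
            if not ids and [c.strip().lower() for c in row[:2]] == ["id", "label"]:
                continue
            ids.append(row[0].strip())
            labels.append(row[1].strip())
    return LabelVector(ids, labels)


def write_labels(lv: LabelVector, path, delimiter: str = "\t"):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["id", "label"])
        for i, l in zip(lv.ids, lv.labels):
            w.writerow([i, l])
    return path


def log_transform(m: OmicsMatrix, pseudocount: float = 1.0, base: float | None = None) -> OmicsMatrix:
    """Replace every observed cell by log(value + pseudocount); mask unchanged.

    ``base=None`` means natural log.
    """
    shifted = m.values + pseudocount
    bad = m.mask & (shifted <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"log_transform: value + pseudocount <= 0 at cell "
            f"({m.feature_ids[i]}, {m.sample_ids[j]}): {m.values[i, j]}"
        )
    out = np.full_like(m.values, np.nan)
    out[m.mask] = np.log(shifted[m.mask])
    if base is not None:
        out[m.mask] /= np.log(base)
    return OmicsMatrix(out, m.mask.copy(), list(m.feature_ids), list(m.sample_ids))
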
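"""Label-matrix data model, file I/O and basic corpus filters.

The universal input of every analysis stage is the :class:`LabelMatrix`: a
binary text-by-distortion incidence matrix with optional per-text metadata
(identifier, character length, thread/group id). Matrices are read and
written as CSV (one binary column per taxonomy label) or JSON-lines (label
names listed per record).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import DistortionTaxonomy

logger = logging.getLogger(__name__)

_META_COLUMNS = ("text_id", "length_chars", "group_id")


class SchemaError(ValueError):
    """A required column is missing from an input file."""


class ValidationError(ValueError):
    """A cell value violates the binary-incidence contract."""


@dataclass
class LabelMatrix:
    """Binary text x distortion incidence matrix.

    Attributes
    ----------
    incidence
        ``(N, D)`` array of 0/1 values; ``incidence[t, i] = 1`` means text
        ``t`` carries distortion label ``i``.
    taxonomy
        The label taxonomy; column ``i`` corresponds to ``taxonomy.labels[i]``.
    text_ids, lengths, groups
        Optional per-text metadata arrays of length ``N``. ``lengths`` holds
        character counts, ``groups`` thread/group identifiers.
    """

    incidence: np.ndarray
    taxonomy: DistortionTaxonomy = field(default_factory=DistortionTaxonomy)
    text_ids: np.ndarray | None = None
    lengths: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence)
        if inc.ndim != 2:
            raise ValidationError("incidence must be 2-dimensional")
        if inc.shape[1] != self.taxonomy.size:
            raise ValidationError(
                f"incidence has {inc.shape[1]} columns, taxonomy has "
                f"{self.taxonomy.size} labels"
            )
        if inc.size and not np.isin(inc, (0, 1)).all():
            bad = np.argwhere(~np.isin(inc, (0, 1)))[0]
            raise ValidationError(
                f"non-binary cell at row {bad[0]}, column "
                f"{self.taxonomy.labels[bad[1]]!r}"
            )
        self.incidence = inc.astype(np.uint8)
        for name in ("text_ids", "lengths", "groups"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if arr.shape[0] != inc.shape[0]:
                    raise ValidationError(f"{name} length mismatch")
                setattr(self, name, arr)

    # -- basic accessors -------------------------------------------------
    @property
    def n_texts(self) -> int:
        return int(self.incidence.shape[0])

    @property
    def n_labels(self) -> int:
        return int(self.incidence.shape[1])

    @property
    def marginals(self) -> np.ndarray:
        """Per-label text counts ``N_i`` (column sums)."""
        return self.incidence.sum(axis=0).astype(np.int64)

    @property
    def labels_per_text(self) -> np.ndarray:
        return self.incidence.sum(axis=1).astype(np.int64)

    def subset(self, rows: np.ndarray) -> "LabelMatrix":
        """A new matrix restricted to *rows* (boolean mask or index array)."""
        rows = np.asarray(rows)
        return LabelMatrix(
            incidence=self.incidence[rows],
            taxonomy=self.taxonomy,
            text_ids=None if self.text_ids is None else self.text_ids[rows],
            lengths=None if self.lengths is None else self.lengths[rows],
            groups=None if self.groups is None else self.groups[rows],
        )

    def copy(self) -> "LabelMatrix":
        return LabelMatrix(
            incidence=self.incidence.copy(),
            taxonomy=self.taxonomy,
            text_ids=None if self.text_ids is None else self.text_ids.copy(),
            lengths=None if self.lengths is None else self.lengths.copy(),
            groups=None if self.groups is None else self.groups.copy(),
        )

    def label_sets(self) -> list[list[str]]:
        """Label names per text, in taxonomy order."""
        labs = np.asarray(self.taxonomy.labels)
        return [list(labs[row.astype(bool)]) for row in self.incidence]


def concat(matrices: Sequence[LabelMatrix]) -> LabelMatrix:
    """Stack matrices over texts (taxonomies must be identical)."""
    if not matrices:
        raise ValueError("nothing to concatenate")
    tax = matrices[0].taxonomy
    if any(m.taxonomy.labels != tax.labels for m in matrices):
        raise ValueError("taxonomies differ")

    def _stack(attr: str):
        parts = [getattr(m, attr) for m in matrices]
        if any(p is None for p in parts):
            return None
        return np.concatenate(parts)

    return LabelMatrix(
        incidence=np.concatenate([m.incidence for m in matrices]),
        taxonomy=tax,
        text_ids=_stack("text_ids"),
        lengths=_stack("lengths"),
        groups=_stack("groups"),
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".csv"}:
        return "csv"
    if suffix in {".jsonl", ".ndjson"}:
        return "jsonl"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_label_matrix(
    path: str | Path,
    format: str | None = None,
    taxonomy: DistortionTaxonomy | None = None,
) -> LabelMatrix:
    """Read a label matrix from CSV or JSON-lines.

    CSV files must contain one binary column per taxonomy label (extra
    columns are preserved only if they are the recognised metadata columns
    ``text_id``, ``length_chars``, ``group_id``; other columns are ignored).
    JSON-lines records carry ``{"labels": [...names...]}`` plus optional
    metadata keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    taxonomy = taxonomy or DistortionTaxonomy()
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _read_csv(path, taxonomy)
    if fmt == "jsonl":
        return _read_jsonl(path, taxonomy)
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: Path, taxonomy: DistortionTaxonomy) -> LabelMatrix:
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [lab for lab in taxonomy.labels if lab not in df.columns]
    if missing:
        raise SchemaError(f"missing label column(s): {missing}")
    inc = df[list(taxonomy.labels)].to_numpy()
    bad = ~np.isin(inc, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"non-binary value {inc[r, c]!r} at row {r}, "
            f"column {taxonomy.labels[c]!r}"
        )
    return LabelMatrix(
        incidence=inc,
        taxonomy=taxonomy,
        text_ids=df["text_id"].to_numpy() if "text_id" in df else None,
        lengths=df["length_chars"].to_numpy() if "length_chars" in df else None,
        groups=df["group_id"].to_numpy() if "group_id" in df else None,
    )


def _read_jsonl(path: Path, taxonomy: DistortionTaxonomy) -> LabelMatrix:
    rows, ids, lens, grps = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            row = np.zeros(taxonomy.size, dtype=np.uint8)
            seen = set()
            for name in rec.get("labels", []):
                idx = taxonomy.index(name)  # KeyError on unknown label
                if idx in seen:
                    raise ValidationError(
                        f"duplicate label {name!r} at line {lineno}"
                    )
                seen.add(idx)
                row[idx] = 1
            rows.append(row)
            ids.append(rec.get("text_id"))
            lens.append(rec.get("length_chars"))
            grps.append(rec.get("group_id"))
    inc = np.array(rows, dtype=np.uint8) if rows else np.zeros((0, taxonomy.size), np.uint8)

    def _opt(vals):
        if all(v is None for v in vals):
            return None
        return np.array(vals, dtype=object)

    lengths = None
    if any(v is not None for v in lens):
        lengths = np.array([np.nan if v is None else v for v in lens], dtype=float)
    return LabelMatrix(
        incidence=inc,
        taxonomy=taxonomy,
        text_ids=_opt(ids),
        lengths=lengths,
        groups=_opt(grps),
    )


def write_label_matrix(m: LabelMatrix, path: str | Path, format: str | None = None) -> None:
    """Write a label matrix as CSV or JSON-lines (round-trip safe)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        df = pd.DataFrame(m.incidence, columns=list(m.taxonomy.labels))
        if m.text_ids is not None:
            df.insert(0, "text_id", m.text_ids)
        if m.lengths is not None:
            df["length_chars"] = m.lengths
        if m.groups is not None:
            df["group_id"] = m.groups
        df.to_csv(path, index=False)
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            sets = m.label_sets()
            for t in range(m.n_texts):
                rec: dict = {"labels": sets[t]}
                if m.text_ids is not None:
                    rec["text_id"] = _jsonable(m.text_ids[t])
                if m.lengths is not None:
                    rec["length_chars"] = _jsonable(m.lengths[t])
                if m.groups is not None:
                    rec["group_id"] = _jsonable(m.groups[t])
                fh.write(json.dumps(rec) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        f = float(v)
        return int(f) if f.is_integer() else f
    return v


# ---------------------------------------------------------------------------
# Corpus filters
# ---------------------------------------------------------------------------

def filter_min_length(m: LabelMatrix, min_chars: int = 200) -> LabelMatrix:
    """Drop texts shorter than *min_chars* characters.

    The boundary is inclusive: a text of exactly *min_chars* characters is
    retained ("shorter than" excludes only strictly smaller lengths).
    """
    if m.lengths is None:
        raise ValueError("length_chars metadata is required for the length filter")
    keep = np.asarray(m.lengths, dtype=float) >= min_chars
    removed = int((~keep).sum())
    out = m.subset(keep)
    if out.n_texts == 0:
        warnings.warn("length filter removed every text", stacklevel=2)
    logger.info("length filter removed %d of %d texts", removed, m.n_texts)
    return out


def drop_unlabeled(m: LabelMatrix) -> LabelMatrix:
    """Drop texts carrying no label at all; logs the removed fraction."""
    keep = m.labels_per_text > 0
    removed = int((~keep).sum())
    frac = removed / m.n_texts if m.n_texts else 0.0
    out = m.subset(keep)
    if m.n_texts and out.n_texts == 0:
        warnings.warn("every text was unlabeled", stacklevel=2)
    logger.info("dropped %d unlabeled texts (%.1f%%)", removed, 100 * frac)
    return out


# ---------------------------------------------------------------------------
# Per-text count summaries
# ---------------------------------------------------------------------------

BUCKETS = ("0", "1-2", "3", "4+")


@dataclass(frozen=True)
class CountDistributionSummary:
    """Distribution of the number of distortions per text.

    ``skewness`` is the adjusted Fisher-Pearson sample skewness;
    ``skewness_p`` is the two-sided p-value of D'Agostino's skewness z-test
    (``None`` when fewer than 8 texts are available).
    """

    mean_per_text: float
    proportion_by_bucket: Mapping[str, float]
    skewness: float
    skewness_p: float | None

    def as_dict(self) -> dict:
        return {
            "mean_per_text": self.mean_per_text,
            "proportion_by_bucket": dict(self.proportion_by_bucket),
            "skewness": self.skewness,
            "skewness_p": self.skewness_p,
        }


def bucket_proportions(counts: np.ndarray) -> dict[str, float]:
    """Proportions of texts with 0, 1-2, 3 and 4+ labels."""
    counts = np.asarray(counts)
    n = counts.size
    if n == 0:
        return {b: 0.0 for b in BUCKETS}
    return {
        "0": float((counts == 0).sum() / n),
        "1-2": float(((counts >= 1) & (counts <= 2)).sum() / n),
        "3": float((counts == 3).sum() / n),
        "4+": float((counts >= 4).sum() / n),
    }


def summarize_counts(m: LabelMatrix) -> CountDistributionSummary:
    """Summarise the per-text label-count distribution."""
    counts = m.labels_per_text
    if counts.size == 0:
        raise ValueError("empty matrix")
    mean = float(counts.sum() / counts.size)
    skew = float(stats.skew(counts, bias=False)) if counts.size > 2 else float("nan")
    skew_p: float | None = None
    if counts.size >= 8 and np.ptp(counts) > 0:
        skew_p = float(stats.skewtest(counts).pvalue)
    return CountDistributionSummary(
        mean_per_text=mean,
        proportion_by_bucket=bucket_proportions(counts),
        skewness=skew,
        skewness_p=skew_p,
    )
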
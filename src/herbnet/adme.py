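"""ADME screening: Tanimoto drug-likeness, OB/DL filtering, and
multi-database compound intersection.

Drug-likeness (DL) of a candidate molecule is its Tanimoto similarity

    f(A, B) = A.B / (|A|^2 + |B|^2 - A.B)

between the molecule's descriptor vector A and a reference descriptor
profile B summarizing known drugs.  Candidates are kept when their
predicted oral bioavailability (OB) and DL both clear inclusive
thresholds (defaults 30% and 0.18).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DimensionError, UndefinedSimilarityError, ValidationError
from .io import CompoundRecord, SourceCatalog


@dataclass(frozen=True)
class ReferenceSet:
    """A bank of drug descriptor vectors (rows) of uniform dimensionality,
    standing in for a large known-drug reference such as a DrugBank
    export.  ``centroid`` is the elementwise mean vector."""

    descriptors: np.ndarray
    label: str = "reference"

    def __post_init__(self) -> None:
        arr = np.asarray(self.descriptors, dtype=float)
        if arr.ndim != 2 or arr.shape[0] == 0:
            raise ValidationError("reference set must be a non-empty 2D array")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("reference descriptors must be finite")
        object.__setattr__(self, "descriptors", arr)

    @property
    def centroid(self) -> np.ndarray:
        return self.descriptors.mean(axis=0)


@dataclass(frozen=True)
class FilterCriteria:
    """Inclusive OB/DL screening thresholds (both comparisons are >=)."""

    ob_min: float = 30.0
    dl_min: float = 0.18

    def __post_init__(self) -> None:
        if self.ob_min < 0:
            raise ValidationError("ob_min must be >= 0")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValidationError("dl_min must be in [0,1]")


def tanimoto_similarity(a, b) -> float:
    """Tanimoto similarity A.B / (|A|^2 + |B|^2 - A.B) of two descriptor
    vectors.

    Symmetric; equals 1 exactly when the vectors are identical and
    non-zero; for non-negative vectors the result lies in [0, 1] and, on
    binary 0/1 vectors, coincides with the Jaccard index of the supports.

    Raises
    ------
    DimensionError
        If the vectors differ in length.
    UndefinedSimilarityError
        If both vectors are all-zero (the ratio is 0/0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise DimensionError("descriptor vectors must be 1-D")
    if a.shape != b.shape:
        raise DimensionError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("descriptor vectors must be finite")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        if not a.any() and not b.any():
            raise UndefinedSimilarityError("both descriptor vectors are all-zero")
        # a == b elementwise and non-zero: numerator equals denominator
        return 1.0
    return dot / denom


def drug_likeness_index(x, ref: ReferenceSet, method: str = "centroid") -> float:
    """Drug-likeness of descriptor vector ``x`` against a reference bank.

    ``method="centroid"`` (default) scores Tanimoto similarity against the
    mean descriptor vector of the reference — the single-B reading of the
    DL formula.  ``method="mean_similarity"`` instead averages the
    per-molecule Tanimoto scores.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != ref.descriptors.shape[1]:
        raise DimensionError(
            f"descriptor length {x.shape[0]} does not match reference "
            f"dimensionality {ref.descriptors.shape[1]}"
        )
    if method == "centroid":
        return tanimoto_similarity(x, ref.centroid)
    if method == "mean_similarity":
        return float(np.mean([tanimoto_similarity(x, row) for row in ref.descriptors]))
    raise ValueError(f"unknown method {method!r}")


@dataclass(frozen=True)
class RejectedCompound:
    record: CompoundRecord
    reason: str  # low_ob | low_dl | both


def filter_compounds(
    records: Sequence[CompoundRecord], crit: FilterCriteria = FilterCriteria()
) -> tuple[list[CompoundRecord], list[RejectedCompound]]:
    """Partition compounds into (kept, rejected) by the inclusive OB/DL
    screen.  Order is preserved; each rejection is annotated with which
    threshold(s) failed."""
    kept: list[CompoundRecord] = []
    rejected: list[RejectedCompound] = []
    for rec in records:
        ob_ok = rec.ob >= crit.ob_min
        dl_ok = rec.dl >= crit.dl_min
        if ob_ok and dl_ok:
            kept.append(rec)
        else:
            reason = "both" if not ob_ok and not dl_ok else ("low_ob" if not ob_ok else "low_dl")
            rejected.append(RejectedCompound(rec, reason))
    return kept, rejected


@dataclass
class IntersectionReport:
    """Membership structure of several database catalogs.

    ``membership`` maps each (canonicalized) compound name to the set of
    catalogs listing it; ``shared_by_all`` is the size of the common
    core; ``by_count[k]`` counts names present in exactly k catalogs;
    ``pairwise[(a, b)]`` gives each pairwise intersection size.
    """

    membership: dict[str, frozenset[str]]
    shared_by_all: int
    by_count: dict[int, int]
    pairwise: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def shared_names(self) -> set[str]:
        n_sources = len({s for ss in self.membership.values() for s in ss})
        return {name for name, ss in self.membership.items() if len(ss) == n_sources}


def intersect_sources(catalogs: Sequence[SourceCatalog]) -> IntersectionReport:
    """Venn-style intersection counts across >= 2 database catalogs."""
    if len(catalogs) < 2:
        raise ValidationError("need at least two catalogs to intersect")
    names = [c.source_name for c in catalogs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate source_name among {names}")
    membership: dict[str, set[str]] = {}
    for cat in catalogs:
        for member in cat.members:
            membership.setdefault(member, set()).add(cat.source_name)
    frozen = {m: frozenset(s) for m, s in membership.items()}
    by_count: dict[int, int] = {k: 0 for k in range(1, len(catalogs) + 1)}
    for srcs in frozen.values():
        by_count[len(srcs)] += 1
    shared_by_all = by_count[len(catalogs)]
    pairwise: dict[tuple[str, str], int] = {}
    for i, a in enumerate(catalogs):
        for b in catalogs[i + 1 :]:
            pairwise[(a.source_name, b.source_name)] = len(a.members & b.members)
    return IntersectionReport(
        membership=frozen, shared_by_all=shared_by_all, by_count=by_count, pairwise=pairwise
    )


def catalogs_from_mapping(mapping: dict[str, Iterable[str]]) -> list[SourceCatalog]:
    """Convenience: build catalogs from {source_name: names}."""
    return [SourceCatalog(name, frozenset(members)) for name, members in mapping.items()]
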
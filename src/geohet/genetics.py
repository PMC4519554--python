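"""Genotype ingestion and observed heterozygosity.

Observed heterozygosity (H_O) summarizes the genetic diversity of a group of
individuals as the proportion of heterozygous genotype calls averaged over
loci,

    H_O = (1/l) * sum_j h_j,

where ``h_j`` is the fraction of heterozygotes at locus ``j`` among the
individuals with a non-missing call, and ``l`` the number of loci with at
least one call.  The raw value in [0, 1] is rescaled to a percentage in
[0, 100] so that the interpolated surfaces built downstream carry values on a
readable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "HeterozygosityValue",
    "observed_heterozygosity",
    "per_unit_heterozygosity",
]


@dataclass
class GenotypeMatrix:
    """Subjects x loci biallelic genotype codes.

    Codes: 0 and 2 are the two homozygotes, 1 the heterozygote and
    :data:`MISSING` (-1) a failed call.  ``loci`` is a DataFrame with one row
    per locus carrying ``locus_id``, ``locus_class`` (``intragenic`` /
    ``intergenic``) and, optionally, ``maf`` (minor-allele frequency).
    """

    subject_ids: list
    codes: np.ndarray
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D subjects x loci array")
        if self.codes.shape != (len(self.subject_ids), len(self.loci)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.loci)} loci"
            )
        bad = set(np.unique(self.codes)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("subject ids are not unique")
        if self.loci["locus_id"].duplicated().any():
            raise ValueError("locus ids are not unique")
        self._row_index = {s: i for i, s in enumerate(self.subject_ids)}

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls."""
        return (self.codes != MISSING).mean(axis=0)

    def rows(self, subject_subset: Iterable) -> np.ndarray:
        """Row indices for a subject subset, in stored order."""
        idx = []
        for s in subject_subset:
            if s not in self._row_index:
                raise KeyError(f"unknown subject id: {s!r}")
            idx.append(self._row_index[s])
        return np.array(sorted(idx), dtype=int)

    def select_loci(self, locus_class: str) -> "GenotypeMatrix":
        """Restrict to one locus class (``intragenic`` or ``intergenic``)."""
        keep = (self.loci["locus_class"] == locus_class).to_numpy()
        if not keep.any():
            raise ValueError(f"no loci of class {locus_class!r}")
        return GenotypeMatrix(
            subject_ids=list(self.subject_ids),
            codes=self.codes[:, keep],
            loci=self.loci.loc[keep].reset_index(drop=True),
        )

    # ---- I/O ---------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        """Read a genotype CSV: first column subject id, remaining columns one
        locus each (header = locus ids); empty cells are missing."""
        df = pd.read_csv(path, index_col=0, dtype=str)
        codes = df.fillna(str(MISSING)).astype(int).to_numpy()
        loci = pd.DataFrame(
            {"locus_id": df.columns, "locus_class": "intergenic", "maf": np.nan}
        )
        return cls(subject_ids=list(df.index), codes=codes, loci=loci)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.codes, index=pd.Index(self.subject_ids, name="subject_id"),
            columns=self.loci["locus_id"],
        )
        df.to_csv(path)

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Read diploid genotypes from a VCF (biallelic sites only).

        GT conventions: 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> missing.
        """
        from cyvcf2 import VCF  # optional dependency

        vcf = VCF(str(path))
        subject_ids = list(vcf.samples)
        columns, ids = [], []
        for var in vcf:
            if len(var.ALT) != 1:
                raise ValueError(
                    f"multi-allelic site not supported: {var.CHROM}:{var.POS}"
                )
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING)
            columns.append(col.astype(np.int8))
            ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        loci = pd.DataFrame({"locus_id": ids, "locus_class": "intergenic", "maf": np.nan})
        return cls(subject_ids=subject_ids, codes=np.column_stack(columns), loci=loci)


@dataclass(frozen=True)
class HeterozygosityValue:
    """Observed heterozygosity of one group, as a percentage."""

    value: float  # percent, in [0, 100]
    n_subjects: int
    n_loci_used: int


def observed_heterozygosity(
    geno: GenotypeMatrix, subject_subset: Iterable | None = None
) -> HeterozygosityValue:
    """Observed heterozygosity of a subject subset, averaged over loci.

    Per-locus heterozygote proportions use complete-case denominators (the
    number of non-missing calls at that locus within the subset); loci with no
    callable genotype in the subset are dropped from the average.

    Raises
    ------
    ValueError
        If the subset is empty ("no subjects") or every call is missing
        ("no callable loci").
    """
    if subject_subset is None:
        rows = np.arange(geno.n_subjects)
    else:
        rows = geno.rows(subject_subset)
    if rows.size == 0:
        raise ValueError("no subjects in subset")
    sub = geno.codes[rows]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    usable = n_called > 0
    if not usable.any():
        raise ValueError("no callable loci in subset")
    n_het = (sub == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        h_j = n_het[usable] / n_called[usable]
    return HeterozygosityValue(
        value=100.0 * float(h_j.mean()),
        n_subjects=int(rows.size),
        n_loci_used=int(usable.sum()),
    )


def per_unit_heterozygosity(
    geno: GenotypeMatrix,
    membership: Mapping,
    subject_filter: Callable[[object], bool] | None = None,
    units: Sequence | None = None,
) -> pd.DataFrame:
    """Observed heterozygosity per land unit.

    Parameters
    ----------
    membership
        Mapping subject id -> unit id for every subject to include.
    subject_filter
        Optional predicate on subject ids (e.g. natives only); subjects
        failing it contribute to no unit.
    units
        Known unit ids. Defaults to the units appearing in ``membership``;
        when given, a membership value outside it is an error, and listed
        units with no (filtered) subject appear as rows of NaN (absent, not
        zero).

    Returns
    -------
    DataFrame indexed by unit id with columns ``value``, ``n_subjects``,
    ``n_loci_used``.
    """
    by_unit: dict = {}
    known = None if units is None else set(units)
    for subj, unit in membership.items():
        if known is not None and unit not in known:
            raise KeyError(f"unknown unit id in membership: {unit!r}")
        if subject_filter is not None and not subject_filter(subj):
            continue
        by_unit.setdefault(unit, []).append(subj)
    index = list(units) if units is not None else sorted(by_unit, key=str)
    rows = {}
    for unit in index:
        members = by_unit.get(unit, [])
        if not members:
            rows[unit] = (np.nan, 0, 0)
            continue
        hv = observed_heterozygosity(geno, members)
        rows[unit] = (hv.value, hv.n_subjects, hv.n_loci_used)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["value", "n_subjects", "n_loci_used"]
    )
    out.index.name = "unit_id"
    return out
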
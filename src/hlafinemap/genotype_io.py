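"""Cohort genotype tables, SNP tables and reference haplotype frequencies.

The tabular dialects handled here are deliberately plain:

* **HLA genotype TSV** — one row per subject with an id column, a phenotype
  column (``case``/``control``), a ``sex`` column (``F``/``M``/``U``) and two
  columns per locus named ``<LOCUS>_1``/``<LOCUS>_2`` (e.g. ``DRB1_1``).  A
  locus with both cells empty is MISSING for that subject; exactly one empty
  cell is a half-call and rejected.  Any further columns are carried through
  as opaque per-subject clinical strings.
* **SNP genotype TSV** — one row per SNP with ``rsid chrom pos ref alt``
  metadata columns followed by one genotype column per subject id holding the
  number of ALT-allele copies (0/1/2) or ``NA``.
* **Haplotype frequency TSV** — columns ``drb1 dqb1 freq``; frequencies may
  sum to less than one (residual mass belongs to unlisted haplotypes).

Allele nomenclature is normalised on input: an optional ``HLA-`` prefix, the
locus name and the ``*`` separator are stripped, so ``HLA-DRB1*13:02``,
``DRB1*13:02`` and ``13:02`` in a DRB1 column all mean the same allele.
Slash-joined ambiguity groups such as ``02:01/07/18`` are atomic labels:
carrying the group is *not* carrying ``02:01``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven loci supported throughout the pipeline.
LOCI: tuple[str, ...] = ("A", "B", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")

#: Missing-genotype sentinel in SNP matrices.
SNP_MISSING: int = -1

# Two-field allele or slash-joined ambiguity group; two-digit single-field
# group labels (e.g. "A*11") produced by some typing chemistries are also
# accepted.
_ALLELE_RE = re.compile(r"^(?:\d{2}|\d{2,}:\d{2,}(?:/\d{2,})*)$")


class GenotypeParseError(ValueError):
    """Malformed genotype content (allele strings, half-calls, bad values)."""


class SchemaError(ValueError):
    """Structurally invalid table (missing/duplicate columns, bad loci)."""


@dataclass(frozen=True, order=True)
class AlleleCall:
    """One HLA allele label: a locus plus a two-field name or ambiguity group."""

    locus: str
    name: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise SchemaError(f"unsupported locus {self.locus!r}")
        if not _ALLELE_RE.match(self.name):
            raise GenotypeParseError(
                f"malformed allele name {self.name!r} at locus {self.locus}"
            )

    def __str__(self) -> str:  # canonical display form
        return f"{self.locus}*{self.name}"


def parse_allele(text: str, locus: str | None = None) -> AlleleCall:
    """Parse an allele label, normalising ``HLA-``/locus/``*`` decorations.

    ``parse_allele("HLA-DRB1*13:02")``, ``parse_allele("DRB1*13:02")`` and
    ``parse_allele("13:02", locus="DRB1")`` are equivalent.
    """
    raw = text.strip()
    if raw.upper().startswith("HLA-"):
        raw = raw[4:]
    if "*" in raw:
        prefix, _, name = raw.partition("*")
        prefix = prefix.strip().upper()
        if prefix:
            if locus is not None and prefix != locus:
                raise GenotypeParseError(
                    f"allele {text!r} names locus {prefix} but column is {locus}"
                )
            locus = prefix
    else:
        name = raw
    if locus is None:
        raise GenotypeParseError(f"cannot infer locus for allele {text!r}")
    return AlleleCall(locus=locus, name=name.strip())


# A locus genotype is an unordered pair of AlleleCall, or None when MISSING.
LocusGenotype = tuple[AlleleCall, AlleleCall] | None


@dataclass
class Subject:
    """One study subject: phenotype, sex, per-locus HLA genotypes, clinical."""

    id: str
    phenotype: str  # "case" | "control"
    sex: str = "U"  # "F" | "M" | "U"
    hla: dict[str, LocusGenotype] = field(default_factory=dict)
    clinical: dict[str, str] = field(default_factory=dict)

    @property
    def is_case(self) -> bool:
        return self.phenotype == "case"

    def genotype(self, locus: str) -> LocusGenotype:
        return self.hla.get(locus)

    def carries(self, allele: AlleleCall) -> bool | None:
        """True/False carrier status; None when the locus is untyped."""
        g = self.hla.get(allele.locus)
        if g is None:
            return None
        return allele in g


@dataclass(frozen=True)
class SnpRecord:
    """Biallelic SNP metadata (1-based GRCh37 coordinates)."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str


@dataclass
class Cohort:
    """Subjects plus an optional shared SNP map and genotype matrix.

    ``snp_matrix`` has shape (n_subjects, n_snps), dtype int8, with values in
    {0, 1, 2} counting ALT copies and ``SNP_MISSING`` (−1) for no-calls.
    """

    subjects: list[Subject]
    snps: list[SnpRecord] = field(default_factory=list)
    snp_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self._locus_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if self.snp_matrix is not None:
            if self.snp_matrix.shape != (len(self.subjects), len(self.snps)):
                raise SchemaError(
                    "snp_matrix shape does not match subjects x snps"
                )

    # ------------------------------------------------------------------ masks
    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_cases(self) -> int:
        return int(self.case_mask().sum())

    @property
    def n_controls(self) -> int:
        return len(self.subjects) - self.n_cases

    def case_mask(self) -> np.ndarray:
        return np.fromiter(
            (s.is_case for s in self.subjects), dtype=bool, count=len(self.subjects)
        )

    def _locus_arrays(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """Object arrays of the two allele names at a locus (None = missing)."""
        cached = self._locus_cache.get(locus)
        if cached is not None:
            return cached
        n = len(self.subjects)
        a1 = np.empty(n, dtype=object)
        a2 = np.empty(n, dtype=object)
        for i, s in enumerate(self.subjects):
            g = s.hla.get(locus)
            if g is not None:
                a1[i], a2[i] = g[0].name, g[1].name
        self._locus_cache[locus] = (a1, a2)
        return a1, a2

    def typed_mask(self, locus: str) -> np.ndarray:
        a1, _ = self._locus_arrays(locus)
        return np.not_equal(a1, None)

    def carrier_mask(self, allele: AlleleCall) -> np.ndarray:
        """Boolean carrier mask (False where untyped — pair with typed_mask)."""
        a1, a2 = self._locus_arrays(allele.locus)
        return np.equal(a1, allele.name) | np.equal(a2, allele.name)

    def alleles_at(self, locus: str) -> list[AlleleCall]:
        """Distinct alleles observed at a locus, sorted by name."""
        seen: set[str] = set()
        for s in self.subjects:
            g = s.hla.get(locus)
            if g is not None:
                seen.update((g[0].name, g[1].name))
        return [AlleleCall(locus, n) for n in sorted(seen)]

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset sharing the SNP map (matrix sliced accordingly)."""
        idx = np.flatnonzero(mask)
        subs = [self.subjects[i] for i in idx]
        mat = self.snp_matrix[idx] if self.snp_matrix is not None else None
        return Cohort(subjects=subs, snps=self.snps, snp_matrix=mat)

    def with_phenotypes(self, case_mask: np.ndarray) -> "Cohort":
        """Same subjects with relabelled phenotypes (for permutation nulls)."""
        subs = [
            replace(s, phenotype="case" if c else "control")
            for s, c in zip(self.subjects, case_mask)
        ]
        return Cohort(subjects=subs, snps=self.snps, snp_matrix=self.snp_matrix)


@dataclass
class HaplotypeFreqTable:
    """Reference DRB1–DQB1 haplotype frequencies (residual mass allowed)."""

    entries: list[tuple[AlleleCall, AlleleCall, float]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        total = 0.0
        for drb1, dqb1, freq in self.entries:
            if drb1.locus != "DRB1" or dqb1.locus != "DQB1":
                raise SchemaError("haplotype entries must be (DRB1, DQB1) pairs")
            if freq < 0:
                raise ValueError(f"negative haplotype frequency {freq}")
            key = (drb1.name, dqb1.name)
            if key in seen:
                raise ValueError(f"duplicate haplotype entry {drb1}-{dqb1}")
            seen.add(key)
            total += freq
        if total > 1.0 + 1e-6:
            raise ValueError(f"haplotype frequencies sum to {total} > 1")
        self._freq = {(d.name, q.name): f for d, q, f in self.entries}

    @property
    def residual_mass(self) -> float:
        return max(0.0, 1.0 - sum(self._freq.values()))

    def freq(self, drb1: str, dqb1: str, default: float = 0.0) -> float:
        return self._freq.get((drb1, dqb1), default)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SPECIAL_HLA_COLS = ("sex",)


def _is_na(value: object) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() in ("", "NA", "nan")
    )


def read_hla_table(
    path: str | Path,
    phenotype_column: str = "phenotype",
    id_column: str = "id",
) -> Cohort:
    """Read an HLA genotype TSV into a :class:`Cohort`.

    Raises :class:`SchemaError` for structural problems and
    :class:`GenotypeParseError` for malformed alleles or half-calls, naming
    the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (id_column, phenotype_column):
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    locus_cols: dict[str, tuple[str, str]] = {}
    extra_cols: list[str] = []
    for col in df.columns:
        if col in (id_column, phenotype_column) or col in _SPECIAL_HLA_COLS:
            continue
        if col.endswith(("_1", "_2")):
            locus = col[:-2]
            if locus not in LOCI:
                raise SchemaError(f"unknown locus column {col!r}")
            c1, c2 = f"{locus}_1", f"{locus}_2"
            if c1 not in df.columns or c2 not in df.columns:
                raise SchemaError(f"locus {locus} needs both {c1} and {c2}")
            locus_cols[locus] = (c1, c2)
        else:
            extra_cols.append(col)

    subjects: list[Subject] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        phen = str(rec[phenotype_column]).strip().lower()
        if phen not in ("case", "control"):
            raise GenotypeParseError(
                f"line {row_no}: phenotype must be case/control, got {phen!r}"
            )
        sex = str(rec.get("sex", "U")).strip() or "U"
        if _is_na(sex):
            sex = "U"
        hla: dict[str, LocusGenotype] = {}
        for locus, (c1, c2) in locus_cols.items():
            v1, v2 = rec[c1], rec[c2]
            na1, na2 = _is_na(v1), _is_na(v2)
            if na1 and na2:
                continue  # MISSING locus
            if na1 or na2:
                raise GenotypeParseError(
                    f"line {row_no}: half-call at locus {locus} "
                    f"(one of two alleles missing)"
                )
            try:
                hla[locus] = (
                    parse_allele(str(v1), locus),
                    parse_allele(str(v2), locus),
                )
            except GenotypeParseError as exc:
                raise GenotypeParseError(f"line {row_no}: {exc}") from exc
        clinical = {
            c: str(rec[c]) for c in extra_cols if not _is_na(rec[c])
        }
        subjects.append(
            Subject(
                id=str(rec[id_column]),
                phenotype=phen,
                sex=sex,
                hla=hla,
                clinical=clinical,
            )
        )

    cohort = Cohort(subjects=subjects)
    logger.info(
        "read %d cases / %d controls from %s",
        cohort.n_cases,
        cohort.n_controls,
        path,
    )
    for locus in LOCI:
        typed = cohort.typed_mask(locus)
        if typed.any():
            cm = cohort.case_mask()
            logger.info(
                "  %s typed: %d cases / %d controls",
                locus,
                int((typed & cm).sum()),
                int((typed & ~cm).sum()),
            )
    return cohort


def write_hla_table(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort's HLA genotypes back to the TSV dialect of record."""
    loci = [L for L in LOCI if cohort.typed_mask(L).any()]
    cols = ["id", "phenotype", "sex"]
    for L in loci:
        cols += [f"{L}_1", f"{L}_2"]
    clin_keys = sorted({k for s in cohort.subjects for k in s.clinical})
    cols += clin_keys
    rows = []
    for s in cohort.subjects:
        row: dict[str, str] = {"id": s.id, "phenotype": s.phenotype, "sex": s.sex}
        for L in loci:
            g = s.hla.get(L)
            row[f"{L}_1"] = g[0].name if g else ""
            row[f"{L}_2"] = g[1].name if g else ""
        for k in clin_keys:
            row[k] = s.clinical.get(k, "")
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_snp_table(path: str | Path, cohort: Cohort) -> Cohort:
    """Attach a SNP genotype TSV to a cohort, returning a new Cohort.

    Subjects present in the cohort but absent from the SNP table receive
    all-missing genotype vectors (with a warning).
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chrom": str})
    meta = ["rsid", "chrom", "pos", "ref", "alt"]
    for col in meta:
        if col not in df.columns:
            raise SchemaError(f"missing SNP metadata column {col!r}")
    if df["rsid"].duplicated().any():
        dupes = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
        raise SchemaError(f"duplicated rsid(s): {dupes[:5]}")
    pos = df["pos"].to_numpy()
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise SchemaError("SNP positions must be strictly increasing")

    snps = [
        SnpRecord(r.rsid, str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples(index=False)
    ]
    n_sub, n_snp = len(cohort.subjects), len(snps)
    matrix = np.full((n_sub, n_snp), SNP_MISSING, dtype=np.int8)
    sub_cols = [c for c in df.columns if c not in meta]
    known_ids = {s.id for s in cohort.subjects}
    unknown = [c for c in sub_cols if c not in known_ids]
    if unknown:
        raise SchemaError(f"SNP table column(s) not in cohort: {unknown[:5]}")
    col_of = {c: j for j, c in enumerate(sub_cols)}
    geno = df[sub_cols].to_numpy(dtype=object) if sub_cols else None
    for i, s in enumerate(cohort.subjects):
        j = col_of.get(s.id)
        if j is None:
            logger.warning("subject %s absent from SNP table; all-missing", s.id)
            continue
        col = geno[:, j]
        for k, v in enumerate(col):
            if _is_na(v):
                continue
            try:
                g = int(v)
            except (TypeError, ValueError):
                raise GenotypeParseError(
                    f"SNP genotype {v!r} for subject {s.id} not in 0/1/2/NA"
                ) from None
            if g not in (0, 1, 2):
                raise GenotypeParseError(
                    f"SNP genotype {g} for subject {s.id} not in 0/1/2/NA"
                )
            matrix[i, k] = g
    return Cohort(subjects=cohort.subjects, snps=snps, snp_matrix=matrix)


def write_snp_table(cohort: Cohort, path: str | Path) -> None:
    if cohort.snp_matrix is None:
        raise SchemaError("cohort has no SNP data to write")
    cols = {
        "rsid": [r.rsid for r in cohort.snps],
        "chrom": [r.chrom for r in cohort.snps],
        "pos": [r.pos for r in cohort.snps],
        "ref": [r.ref_allele for r in cohort.snps],
        "alt": [r.alt_allele for r in cohort.snps],
    }
    geno = cohort.snp_matrix.astype(object)
    for i, s in enumerate(cohort.subjects):
        cols[s.id] = [
            "NA" if g == SNP_MISSING else str(g) for g in geno[i]
        ]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_haplotype_freqs(path: str | Path) -> HaplotypeFreqTable:
    df = pd.read_csv(path, sep="\t", dtype={"drb1": str, "dqb1": str})
    for col in ("drb1", "dqb1", "freq"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in haplotype table")
    entries = [
        (
            parse_allele(str(r.drb1), "DRB1"),
            parse_allele(str(r.dqb1), "DQB1"),
            float(r.freq),
        )
        for r in df.itertuples(index=False)
    ]
    return HaplotypeFreqTable(entries=entries)


def write_haplotype_freqs(table: HaplotypeFreqTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "drb1": [d.name for d, _, _ in table.entries],
            "dqb1": [q.name for _, q, _ in table.entries],
            "freq": [f for _, _, f in table.entries],
        }
    ).to_csv(path, sep="\t", index=False)


def read_snp_vcf(path: str | Path, cohort: Cohort) -> Cohort:
    """Optional VCF (v4.2) adapter: GT fields become ALT-copy counts.

    Requires ``cyvcf2``.  Multi-allelic records are rejected; the TSV dialect
    remains the format of record.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    vcf = VCF(str(path), gts012=True)
    sample_of = {sid: i for i, sid in enumerate(vcf.samples)}
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise SchemaError(f"multi-allelic record at {var.CHROM}:{var.POS}")
        snps.append(
            SnpRecord(
                var.ID or f"{var.CHROM}:{var.POS}",
                str(var.CHROM).removeprefix("chr"),
                int(var.POS),
                var.REF,
                var.ALT[0],
            )
        )
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012), 3=unknown
        types = var.gt_types
        col = np.where(types == 3, SNP_MISSING, types).astype(np.int8)
        columns.append(col)
    vcf.close()
    n_sub = len(cohort.subjects)
    matrix = np.full((n_sub, len(snps)), SNP_MISSING, dtype=np.int8)
    for i, s in enumerate(cohort.subjects):
        j = sample_of.get(s.id)
        if j is None:
            logger.warning("subject %s absent from VCF; all-missing", s.id)
            continue
        for k, col in enumerate(columns):
            matrix[i, k] = col[j]
    pos = np.array([r.pos for r in snps])
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise SchemaError("VCF positions must be strictly increasing")
    return Cohort(subjects=cohort.subjects, snps=snps, snp_matrix=matrix)
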
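"""Genomic-interval primitives and readers/writers for the formats the pipeline touches.

All coordinates are normalized to a single internal convention: 0-based,
half-open ``[start, end)``.  BED and BEDPE already use this convention; VCF
positions (1-based) are shifted by one on load.  Only cis (same-chromosome)
loops are representable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an input file does not match any supported format."""


class ValidationError(ValueError):
    """Raised when a record violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``chrom:[start, end)`` in bp."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: [a,b) overlaps [c,d) iff a < d and c < b."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def expand(self, slop: int) -> "GenomicInterval":
        """Pad both ends by ``slop`` bp, clipping the start at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - slop), self.end + slop)


@dataclass(frozen=True)
class Loop:
    """A cis chromatin loop between two non-overlapping anchors.

    Anchors are stored left-to-right (``anchor1.start < anchor2.start``);
    constructors may pass them in either order.
    """

    id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValidationError(f"loop {self.id}: anchors on different chromosomes")
        a1, a2 = self.anchor1, self.anchor2
        if a1.start > a2.start:
            a1, a2 = a2, a1
            object.__setattr__(self, "anchor1", a1)
            object.__setattr__(self, "anchor2", a2)
        if a1.overlaps(a2):
            raise ValidationError(f"loop {self.id}: anchors overlap")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def midpoint_distance(self) -> int:
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)

    @property
    def span(self) -> GenomicInterval:
        """The interval from the left edge of anchor1 to the right edge of anchor2."""
        return GenomicInterval(self.chrom, self.anchor1.start, self.anchor2.end)


@dataclass
class ContactMatrix:
    """One chromosome's binned sparse symmetric Hi-C counts.

    Only the upper triangle (``bin_i <= bin_j``) is stored; symmetry is
    implied.  ``balance_weights`` (per-bin multipliers) are ``None`` until
    :func:`loopscape.hic_quant.balance_matrix` is applied; masked bins carry
    NaN weights and are excluded from balanced queries.
    """

    chrom: str
    resolution: int
    n_bins: int
    counts: sp.csr_matrix
    balance_weights: np.ndarray | None = None
    masked_bins: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        coo = sp.coo_matrix(self.counts)
        if np.any(coo.data < 0):
            raise ValidationError("contact counts must be non-negative")
        if np.any(coo.row > coo.col):
            raise ValidationError("only the upper triangle (i <= j) may be stored")
        self.counts = coo.tocsr()

    @property
    def is_balanced(self) -> bool:
        return self.balance_weights is not None

    def query(self, i: int, j: int, balanced: bool = False) -> float:
        """Symmetric lookup of a single pixel; masked pixels return NaN when balanced."""
        if i > j:
            i, j = j, i
        v = float(self.counts[i, j])
        if not balanced:
            return v
        if self.balance_weights is None:
            raise ValueError("matrix is not balanced")
        w = self.balance_weights[i] * self.balance_weights[j]
        return v * w

    def to_dense(self, balanced: bool = False) -> np.ndarray:
        """Full symmetric dense matrix; masked rows/cols are NaN when balanced."""
        upper = self.counts.toarray()
        dense = upper + np.triu(upper, 1).T
        if not balanced:
            return dense
        if self.balance_weights is None:
            raise ValueError("matrix is not balanced")
        w = self.balance_weights
        return dense * np.outer(w, w)

    def triplets(self) -> pd.DataFrame:
        coo = self.counts.tocoo()
        df = pd.DataFrame({"bin_i": coo.row, "bin_j": coo.col, "count": coo.data})
        return df.sort_values(["bin_i", "bin_j"]).reset_index(drop=True)


@dataclass
class GenotypeMatrix:
    """Biallelic variants x samples alternate-allele dosages in {0, 1, 2}.

    Missing genotypes are NaN.  ``maf`` is computed from called genotypes
    only.  Variant positions are 0-based internally.
    """

    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt
    samples: list[str]
    dosages: np.ndarray  # (n_variants, n_samples), float with NaN for missing

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValidationError("dosage matrix dimensions inconsistent")

    @property
    def maf(self) -> np.ndarray:
        return np.array([_maf(row) for row in self.dosages])

    def is_het(self) -> np.ndarray:
        """Boolean (variants x samples) heterozygosity flags (dosage == 1)."""
        return self.dosages == 1

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.dosages[np.asarray(mask)],
        )


def _maf(dosages: np.ndarray) -> float:
    called = dosages[~np.isnan(dosages)]
    if called.size == 0:
        return np.nan
    af = called.sum() / (2 * called.size)
    return min(af, 1 - af)


@dataclass
class SampleMetadata:
    """Per-sample covariates used throughout the regressions."""

    table: pd.DataFrame  # index: sample_id; columns include cell_type, condition, sex

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValidationError("sample_ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# contact matrices (sparse triplet text)
# ---------------------------------------------------------------------------

def load_contact_matrix(
    path: str | Path,
    chrom: str,
    resolution: int,
    chrom_length: int | None = None,
    n_bins: int | None = None,
) -> ContactMatrix:
    """Read a sparse triplet text file (``bin_i bin_j count`` per line).

    Lines starting with ``#`` are comments; a ``#chrom_length=`` /
    ``#resolution=`` header written by :func:`write_contact_matrix` supplies
    the matrix extent when the caller does not.  Values on the lower triangle
    are folded onto the upper triangle.
    """
    path = Path(path)
    rows, cols, vals = [], [], []
    header: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, val = line.lstrip("#").partition("=")
                    try:
                        header[key.strip()] = int(val)
                    except ValueError:
                        pass
                continue
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns (bin_i bin_j count), "
                    f"got {len(parts)}"
                )
            try:
                i, j = int(parts[0]), int(parts[1])
                c = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric triplet") from exc
            if c < 0:
                raise ValidationError(f"{path}:{lineno}: negative count {c}")
            if i > j:
                i, j = j, i
            rows.append(i)
            cols.append(j)
            vals.append(c)
    if n_bins is None:
        if chrom_length is None:
            chrom_length = header.get("chrom_length")
        if chrom_length is not None:
            n_bins = -(-chrom_length // resolution)
        elif rows:
            n_bins = max(max(rows), max(cols)) + 1
        else:
            raise FormatError(
                f"{path}: empty triplet file and no chrom_length/n_bins given"
            )
    mat = sp.coo_matrix(
        (vals, (rows, cols)), shape=(n_bins, n_bins)
    ).tocsr()
    mat.sum_duplicates()
    return ContactMatrix(chrom=chrom, resolution=resolution, n_bins=n_bins, counts=mat)


def write_contact_matrix(matrix: ContactMatrix, path: str | Path) -> None:
    """Write upper-triangle triplets with a small metadata header."""
    with open(path, "w") as fh:
        fh.write(f"#chrom={matrix.chrom}\n")
        fh.write(f"#resolution={matrix.resolution}\n")
        fh.write(f"#chrom_length={matrix.n_bins * matrix.resolution}\n")
        trip = matrix.triplets()
        for i, j, c in trip.itertuples(index=False):
            c = float(c)
            fh.write(f"{int(i)}\t{int(j)}\t{c:g}\n")


# ---------------------------------------------------------------------------
# regions (BED, BEDPE, TSS tables)
# ---------------------------------------------------------------------------

def load_regions(
    path: str | Path, kind: str
) -> list[GenomicInterval] | list[Loop] | list[tuple[str, GenomicInterval]]:
    """Load BED intervals, BEDPE loops, or a gene/TSS table.

    ``kind``:
      * ``bed`` -> list of :class:`GenomicInterval` (name column ignored)
      * ``bedpe`` -> list of :class:`Loop`; trans rows (chrom1 != chrom2) are
        skipped with a warning, anchors are normalized left-to-right
      * ``tss_table`` -> list of ``(gene_id, tss_interval)`` from a BED-like
        TSV ``chrom  start  end  gene_id``
    """
    path = Path(path)
    if kind == "bed":
        return _load_bed(path)
    if kind == "bedpe":
        return _load_bedpe(path)
    if kind == "tss_table":
        return [(name, iv) for iv, name in _iter_bed_named(path)]
    raise FormatError(f"unknown region kind {kind!r}")


def _iter_bed_named(path: Path) -> Iterable[tuple[GenomicInterval, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            yield GenomicInterval(chrom, start, end), name


def _load_bed(path: Path) -> list[GenomicInterval]:
    return [iv for iv, _ in _iter_bed_named(path)]


def _load_bedpe(path: Path) -> list[Loop]:
    loops: list[Loop] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            c1, s1, e1, c2, s2, e2 = parts[:6]
            if c1 != c2:
                skipped += 1
                continue
            s1, e1, s2, e2 = int(s1), int(e1), int(s2), int(e2)
            if e1 <= s1 or e2 <= s2:
                raise ValidationError(f"{path}:{lineno}: end <= start")
            name = parts[6] if len(parts) > 6 else f"loop_{lineno}"
            loops.append(
                Loop(name, GenomicInterval(c1, s1, e1), GenomicInterval(c2, s2, e2))
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} trans (inter-chromosomal) rows")
    return loops


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t"
                f"{a2.chrom}\t{a2.start}\t{a2.end}\t{lp.id}\n"
            )


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names is not None else f"region_{k}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# genotypes (minimal VCF)
# ---------------------------------------------------------------------------

def load_genotypes_vcf(path: str | Path, maf_min: float = 0.05) -> GenotypeMatrix:
    """Load biallelic genotypes from a VCF, keeping variants with MAF > ``maf_min``.

    Dosage is the alternate-allele count per sample; missing genotypes are
    NaN.  Multi-allelic records and records at or below the MAF threshold
    (strict ``>``) are dropped.  Positions are converted to the internal
    0-based convention.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValidationError(f"{path}: VCF has no samples")
    var_rows = []
    dosage_rows = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gts = rec.gt_types.astype(float)
        dos = np.where(gts == 0, 0.0, np.where(gts == 1, 1.0, np.where(gts == 3, 2.0, np.nan)))
        m = _maf(dos)
        if not np.isfinite(m) or m <= maf_min:
            continue
        var_rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS - 1,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        dosage_rows.append(dos)
    variants = pd.DataFrame(
        var_rows, columns=["id", "chrom", "pos", "ref", "alt"]
    )
    dosages = (
        np.array(dosage_rows) if dosage_rows else np.empty((0, len(samples)))
    )
    return GenotypeMatrix(variants=variants, samples=samples, dosages=dosages)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 (CHROM..FORMAT + GT) from a dosage matrix."""
    chroms = list(dict.fromkeys(genotypes.variants["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for k, row in enumerate(genotypes.variants.itertuples(index=False)):
            gts = [
                gt_map.get(d, "./.") if np.isfinite(d) else "./."
                for d in genotypes.dosages[k]
            ]
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# feature x sample tables
# ---------------------------------------------------------------------------

def load_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV count/value matrix (first column feature id, header sample ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


def overlapping_pairs(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) with a[i] overlapping b[j], half-open semantics.

    Sort + sweep over interval ends; used by anchor/peak assignment steps.
    """
    out: list[tuple[int, int]] = []
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, iv in enumerate(b):
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, j))
    for lst in by_chrom.values():
        lst.sort()
    for i, iv in enumerate(a):
        lst = by_chrom.get(iv.chrom, [])
        starts = [x[0] for x in lst]
        lo = np.searchsorted(starts, iv.end, side="left")
        for start, end, j in lst[:lo]:
            if end > iv.start:
                out.append((i, j))
    return out
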
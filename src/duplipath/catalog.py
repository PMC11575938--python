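"""Gene catalog handling for the allotetraploid cotton gene census.

Upland cotton (*Gossypium hirsutum*) carries two parental subgenomes, A and D;
gene copies derived from the same ancestral locus on the two subgenomes are
called At- and Dt-homoeologs.  This module parses the ``Gohir.`` gene-identifier
grammar, pairs homoeologs across subgenomes, and produces the locus/family
census and protein-similarity summaries used throughout the pipeline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "GeneIdentity",
    "GeneRecord",
    "GeneCatalog",
    "LocusSummary",
    "SimilarityResult",
    "GeneIdError",
    "CatalogError",
    "parse_gene_id",
    "format_gene_id",
    "pair_homoeologs",
    "summarize_loci",
    "family_census",
    "pairwise_similarity",
    "similarity_matrix",
]


class GeneIdError(ValueError):
    """Raised when a gene identifier does not follow the Gohir grammar."""


class CatalogError(ValueError):
    """Raised on inconsistent catalog data (e.g. same-subgenome partners)."""


# Gohir.<A|D><2-digit chromosome>G<6-digit locus>[extra digits]
# Extra trailing digits occur in real identifiers such as Gohir.A09G192401.
_GENE_ID_RE = re.compile(
    r"^Gohir\.(?P<sub>[AD])(?P<chrom>\d{2})G(?P<locus>\d{6})(?P<suffix>\d+)?$"
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYBXZJUO*")


@dataclass(frozen=True)
class GeneIdentity:
    """Parsed components of a ``Gohir.`` gene identifier.

    ``subgenome`` is ``"At"`` or ``"Dt"``; ``chromosome`` is 1-13;
    ``locus_number`` is the 6-digit positional number; ``suffix`` carries any
    extra trailing digits (used by split models such as Gohir.A09G192401).
    """

    raw_id: str
    subgenome: str
    chromosome: int
    locus_number: int
    suffix: int | None = None


def parse_gene_id(raw: str) -> GeneIdentity:
    """Parse a gene identifier like ``Gohir.A09G161200``.

    Raises :class:`GeneIdError` naming the offending token on malformed input.
    """
    if not raw:
        raise GeneIdError("empty gene identifier")
    m = _GENE_ID_RE.match(raw)
    if m is None:
        raise GeneIdError(f"malformed gene identifier: {raw!r}")
    chrom = int(m.group("chrom"))
    if not 1 <= chrom <= 13:
        raise GeneIdError(f"chromosome {chrom:02d} out of range 01-13 in {raw!r}")
    suffix = m.group("suffix")
    return GeneIdentity(
        raw_id=raw,
        subgenome="At" if m.group("sub") == "A" else "Dt",
        chromosome=chrom,
        locus_number=int(m.group("locus")),
        suffix=int(suffix) if suffix is not None else None,
    )


def format_gene_id(identity: GeneIdentity) -> str:
    """Inverse of :func:`parse_gene_id` (round-trips on valid IDs)."""
    letter = "A" if identity.subgenome == "At" else "D"
    s = f"Gohir.{letter}{identity.chromosome:02d}G{identity.locus_number:06d}"
    if identity.suffix is not None:
        s += str(identity.suffix)
    return s


@dataclass
class GeneRecord:
    gene_id: str
    locus_id: str
    family: str
    subfamily: str = ""
    partner_id: str | None = None
    cds_length: int = 0
    exon_count: int = 1
    role: str = "structural"  # structural enzyme vs regulatory (TF) gene

    @property
    def identity(self) -> GeneIdentity:
        return parse_gene_id(self.gene_id)


@dataclass
class GeneCatalog:
    """Collection of gene records with homoeolog partner annotations."""

    records: list[GeneRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, gene_id: str) -> GeneRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def validate(self) -> None:
        """Check partner symmetry and opposite-subgenome pairing."""
        by_id = {r.gene_id: r for r in self.records}
        for r in self.records:
            if r.partner_id is None:
                continue
            if r.partner_id not in by_id:
                raise CatalogError(
                    f"{r.gene_id}: partner {r.partner_id} absent from catalog"
                )
            p = by_id[r.partner_id]
            if p.partner_id != r.gene_id:
                raise CatalogError(
                    f"asymmetric partner relation {r.gene_id} -> {r.partner_id}"
                )
            if parse_gene_id(r.gene_id).subgenome == parse_gene_id(p.gene_id).subgenome:
                raise CatalogError(
                    f"partners {r.gene_id}/{p.gene_id} lie on the same subgenome"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "locus_id": r.locus_id,
                    "family": r.family,
                    "subfamily": r.subfamily,
                    "partner_id": r.partner_id if r.partner_id is not None else "",
                    "cds_length": r.cds_length,
                    "exon_count": r.exon_count,
                    "role": r.role,
                }
                for r in self.records
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneCatalog":
        records = []
        for row in df.itertuples(index=False):
            partner = getattr(row, "partner_id", "")
            if partner in ("", None) or (isinstance(partner, float) and np.isnan(partner)):
                partner = None
            records.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    locus_id=row.locus_id,
                    family=row.family,
                    subfamily=getattr(row, "subfamily", "") or "",
                    partner_id=partner,
                    cds_length=int(getattr(row, "cds_length", 0)),
                    exon_count=int(getattr(row, "exon_count", 1)),
                    role=getattr(row, "role", "structural") or "structural",
                )
            )
        return cls(records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"partner_id": "string"})
        df["partner_id"] = df["partner_id"].fillna("")
        if "subfamily" in df.columns:
            df["subfamily"] = df["subfamily"].fillna("")
        return cls.from_frame(df)


@dataclass(frozen=True)
class LocusSummary:
    n_dual: int
    n_at_only: int
    n_dt_only: int

    @property
    def n_loci(self) -> int:
        return self.n_dual + self.n_at_only + self.n_dt_only

    @property
    def n_genes(self) -> int:
        return 2 * self.n_dual + self.n_at_only + self.n_dt_only


def pair_homoeologs(
    catalog: GeneCatalog,
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Partition the catalog into (At, Dt) homoeolog pairs and singletons.

    Explicit ``partner_id`` annotations take precedence.  When absent and
    protein ``sequences`` are supplied, unannotated genes are paired by
    reciprocal best global-alignment identity within the same family and
    chromosome number, ties broken by lowest locus number.

    Returns ``(pairs, at_only, dt_only)`` with pairs ordered (At id, Dt id).
    """
    catalog.validate()
    by_id = {r.gene_id: r for r in catalog.records}
    paired: set[str] = set()
    pairs: list[tuple[str, str]] = []

    for r in catalog.records:
        if r.gene_id in paired or r.partner_id is None:
            continue
        ident = parse_gene_id(r.gene_id)
        a, d = (r.gene_id, r.partner_id) if ident.subgenome == "At" else (r.partner_id, r.gene_id)
        pairs.append((a, d))
        paired.update((a, d))

    unpaired = [r for r in catalog.records if r.gene_id not in paired]
    if sequences:
        pairs.extend(_pair_by_similarity(unpaired, sequences, paired))

    at_only = sorted(
        r.gene_id for r in catalog.records
        if r.gene_id not in paired and parse_gene_id(r.gene_id).subgenome == "At"
    )
    dt_only = sorted(
        r.gene_id for r in catalog.records
        if r.gene_id not in paired and parse_gene_id(r.gene_id).subgenome == "Dt"
    )
    pairs.sort()
    return pairs, at_only, dt_only


def _pair_by_similarity(
    unpaired: Sequence[GeneRecord],
    sequences: Mapping[str, str],
    paired: set[str],
) -> list[tuple[str, str]]:
    # Reciprocal best hit within (family, chromosome); deterministic tie-break
    # by lowest locus number of the candidate partner.
    groups: dict[tuple[str, int], dict[str, list[GeneRecord]]] = {}
    for r in unpaired:
        if r.gene_id not in sequences:
            continue
        ident = parse_gene_id(r.gene_id)
        key = (r.family, ident.chromosome)
        groups.setdefault(key, {"At": [], "Dt": []})[ident.subgenome].append(r)

    new_pairs: list[tuple[str, str]] = []
    for key, sides in sorted(groups.items()):
        ats = sorted(sides["At"], key=lambda r: parse_gene_id(r.gene_id).locus_number)
        dts = sorted(sides["Dt"], key=lambda r: parse_gene_id(r.gene_id).locus_number)
        if not ats or not dts:
            continue
        ident_pct = {
            (a.gene_id, d.gene_id): pairwise_similarity(
                sequences[a.gene_id], sequences[d.gene_id]
            ).percent_identity
            for a in ats
            for d in dts
        }

        def best(gene_id: str, candidates: list[GeneRecord], axis: int) -> str:
            scored = [
                (
                    -ident_pct[(gene_id, c.gene_id) if axis == 0 else (c.gene_id, gene_id)],
                    parse_gene_id(c.gene_id).locus_number,
                    c.gene_id,
                )
                for c in candidates
            ]
            return min(scored)[2]

        for a in ats:
            if a.gene_id in paired:
                continue
            d_best = best(a.gene_id, [d for d in dts if d.gene_id not in paired], 0) if any(
                d.gene_id not in paired for d in dts
            ) else None
            if d_best is None:
                continue
            a_best = best(d_best, [x for x in ats if x.gene_id not in paired], 1)
            if a_best == a.gene_id:  # reciprocal best
                new_pairs.append((a.gene_id, d_best))
                paired.update((a.gene_id, d_best))
    return new_pairs


def summarize_loci(catalog: GeneCatalog) -> LocusSummary:
    """Census of dual / At-only / Dt-only loci."""
    pairs, at_only, dt_only = pair_homoeologs(catalog)
    return LocusSummary(n_dual=len(pairs), n_at_only=len(at_only), n_dt_only=len(dt_only))


def family_census(catalog: GeneCatalog, by_subfamily: bool = False) -> pd.DataFrame:
    """Per-family (or per-subfamily) gene and locus counts.

    The grand total of ``n_genes`` equals the catalog size, and the total of
    ``n_loci`` equals the locus summary's count — conservation the tests rely
    on.
    """
    key = "subfamily" if by_subfamily else "family"
    rows = []
    df = catalog.to_frame()
    if df.empty:
        return pd.DataFrame(columns=[key, "n_genes", "n_loci"])
    for name, grp in df.groupby(key, sort=True):
        rows.append({key: name, "n_genes": len(grp), "n_loci": grp["locus_id"].nunique()})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimilarityResult:
    percent_identity: float
    percent_similarity: float
    alignment_length: int


_DEFAULT_MATRIX = "BLOSUM62"


def pairwise_similarity(
    seq_a: str,
    seq_b: str,
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SimilarityResult:
    """Global (end-to-end) protein alignment identity and similarity.

    Identity is the fraction of aligned columns with identical residues;
    similarity additionally counts columns whose substitution score is
    positive.  Both are percentages of the alignment length (gaps included).
    """
    for name, seq in (("first", seq_a), ("second", seq_b)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{name} sequence contains non-amino-acid characters: {sorted(bad)}")

    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    sub = substitution_matrices.load(matrix)
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    col_a, col_b = aln[0], aln[1]

    length = len(col_a)
    n_ident = 0
    n_sim = 0
    for x, y in zip(col_a, col_b):
        if x == "-" or y == "-":
            continue
        if x == y:
            n_ident += 1
            n_sim += 1
        elif sub[x, y] > 0:
            n_sim += 1
    return SimilarityResult(
        percent_identity=100.0 * n_ident / length,
        percent_similarity=100.0 * n_sim / length,
        alignment_length=length,
    )


def similarity_matrix(
    sequences: Mapping[str, str],
    matrix: str = _DEFAULT_MATRIX,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric identity and similarity matrices for a gene family.

    Returns ``(identity, similarity)`` DataFrames with diagonal 100.
    """
    ids = list(sequences)
    if len(ids) < 2:
        raise ValueError("similarity matrix needs at least 2 sequences")
    n = len(ids)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = pairwise_similarity(
                sequences[ids[i]], sequences[ids[j]], matrix, gap_open, gap_extend
            )
            ident[i, j] = ident[j, i] = res.percent_identity
            simil[i, j] = simil[j, i] = res.percent_similarity
    return (
        pd.DataFrame(ident, index=ids, columns=ids),
        pd.DataFrame(simil, index=ids, columns=ids),
    )


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
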
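"""SNP-to-gene assignment, LD pruning and per-gene association summaries.

Candidate genes from the connector search are validated against GWAS
summary statistics.  Each gene claims the SNPs inside its body extended
100 kb up- and downstream; the number of *independent* SNPs per gene is
estimated from pairwise linkage disequilibrium (connected components of
the D' >= 0.8 graph) and used as the Bonferroni denominator.  The
per-gene report carries the smallest raw and corrected p-value, the SNP
counts, and the independent-test count; a replication pass re-tests the
significant SNPs in a second dataset with a Bonferroni over the number
of independent candidates carried forward.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MinaError

DEFAULT_WINDOW_KB = 100
DEFAULT_DPRIME = 0.8
ALPHA = 0.05


@dataclass(frozen=True)
class GeneRecord:
    """A gene with 1-based inclusive coordinates.

    The association window extends ``window_bp`` bases up- and downstream
    of the annotated start and end, clipped at position 1.
    """

    symbol: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise MinaError(
                f"{self.symbol}: invalid coordinates [{self.start}, {self.end}]"
            )

    def window(self, window_bp: int = DEFAULT_WINDOW_KB * 1000) -> tuple[int, int]:
        if window_bp < 0:
            raise MinaError("window size must be >= 0")
        return max(1, self.start - window_bp), self.end + window_bp


@dataclass(frozen=True)
class SnpAssociation:
    """One genotyped SNP with its association p-value."""

    snp_id: str
    chrom: str
    pos: int
    p_value: float

    def __post_init__(self):
        if self.pos < 1:
            raise MinaError(f"{self.snp_id}: position must be >= 1")
        if not 0.0 < self.p_value <= 1.0:
            raise MinaError(f"{self.snp_id}: p-value {self.p_value} outside (0, 1]")


class LdTable:
    """Symmetric pairwise D' lookup; absent pairs default to D' = 0."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._d: dict[frozenset[str], float] = {}
        for (a, b), v in (pairs or {}).items():
            self.set(a, b, v)

    def set(self, a: str, b: str, dprime_value: float) -> None:
        if not 0.0 <= dprime_value <= 1.0:
            raise MinaError(f"D' {dprime_value} outside [0, 1] for {a}/{b}")
        if a == b:
            return
        key = frozenset((a, b))
        old = self._d.get(key)
        if old is not None and not math.isclose(old, dprime_value):
            raise MinaError(f"conflicting D' for {a}/{b}: {old} vs {dprime_value}")
        self._d[key] = dprime_value

    def get(self, a: str, b: str, missing: str = "zero") -> float:
        if a == b:
            return 1.0
        v = self._d.get(frozenset((a, b)))
        if v is None:
            if missing == "zero":
                return 0.0
            raise MinaError(f"no D' recorded for pair {a}/{b}")
        return v

    def __len__(self) -> int:
        return len(self._d)

    def items(self):
        """Sorted (snp_a, snp_b, dprime) triples."""
        out = []
        for key, v in self._d.items():
            a, b = sorted(key)
            out.append((a, b, v))
        return sorted(out)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LdTable":
        """Read columns SNP_A, SNP_B, DPRIME (header required)."""
        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().upper() for c in df.columns]
        needed = {"SNP_A", "SNP_B", "DPRIME"}
        if not needed <= set(df.columns):
            raise MinaError(f"{path}: LD table needs columns {sorted(needed)}")
        table = cls()
        for row in df.itertuples(index=False):
            table.set(str(row.SNP_A), str(row.SNP_B), float(row.DPRIME))
        return table

    @classmethod
    def from_haplotypes(
        cls, haplotypes: np.ndarray, snp_ids: list[str]
    ) -> "LdTable":
        """Compute all pairwise D' from a haplotype matrix (rows =
        haplotypes, columns = SNPs, entries 0/1).  Monomorphic columns
        are skipped with a warning."""
        haplotypes = np.asarray(haplotypes)
        if haplotypes.shape[1] != len(snp_ids):
            raise MinaError("haplotype matrix width != number of SNP ids")
        table = cls()
        poly = [
            j
            for j in range(haplotypes.shape[1])
            if 0 < haplotypes[:, j].sum() < haplotypes.shape[0]
        ]
        skipped = set(range(haplotypes.shape[1])) - set(poly)
        if skipped:
            warnings.warn(
                "monomorphic SNPs skipped: "
                + ", ".join(snp_ids[j] for j in sorted(skipped))
            )
        for i_idx, i in enumerate(poly):
            for j in poly[i_idx + 1 :]:
                a, b = haplotypes[:, i], haplotypes[:, j]
                n = len(a)
                counts = np.array(
                    [
                        [np.sum((a == 1) & (b == 1)), np.sum((a == 1) & (b == 0))],
                        [np.sum((a == 0) & (b == 1)), np.sum((a == 0) & (b == 0))],
                    ]
                )
                table.set(snp_ids[i], snp_ids[j], dprime(counts))
        return table


def dprime(haplotype_counts) -> float:
    """Normalised LD coefficient D' from a 2x2 haplotype count table.

    ``haplotype_counts`` is ``[[n_AB, n_Ab], [n_aB, n_ab]]``.  With
    ``D = p(AB) - p(A)p(B)``, D' is ``|D| / D_max`` where ``D_max`` is
    ``min(p(A)p(b), p(a)p(B))`` for D > 0 and ``min(p(A)p(B), p(a)p(b))``
    for D < 0; D = 0 returns 0.  Monomorphic loci leave D' undefined.
    """
    counts = np.asarray(haplotype_counts, dtype=float)
    if counts.shape != (2, 2) or (counts < 0).any():
        raise MinaError("haplotype counts must be a non-negative 2x2 table")
    total = counts.sum()
    if total < 1:
        raise MinaError("haplotype counts empty")
    pAB = counts[0, 0] / total
    pA = counts[0].sum() / total
    pB = counts[:, 0].sum() / total
    pa, pb = 1.0 - pA, 1.0 - pB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MinaError("undefined D-prime: monomorphic locus")
    d = pAB - pA * pB
    if d == 0.0:
        return 0.0
    dmax = min(pA * pb, pa * pB) if d > 0 else min(pA * pB, pa * pb)
    return abs(d) / dmax


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------

def read_gene_bed(path: str | Path) -> list[GeneRecord]:
    """Read BED3+1 gene coordinates (chrom, start, end, symbol).

    BED's 0-based half-open intervals are converted to the internal
    1-based inclusive convention on read.
    """
    genes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MinaError(f"{path}:{lineno}: BED3+1 needs 4 columns")
            try:
                genes.append(
                    GeneRecord(
                        symbol=fields[3].strip().upper(),
                        chrom=fields[0],
                        start=int(fields[1]) + 1,
                        end=int(fields[2]),
                    )
                )
            except (ValueError, MinaError) as exc:
                raise MinaError(f"{path}:{lineno}: {exc}") from exc
    return genes


def read_gwas(path: str | Path) -> list[SnpAssociation]:
    """Read GWAS summary statistics: TSV with header SNP, CHR, POS, P.

    Extra columns are ignored.  p-values recorded as 0 are floored at the
    smallest positive p in the dataset so downstream -log and correction
    arithmetic stays finite.
    """
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().upper() for c in df.columns]
    needed = {"SNP", "CHR", "POS", "P"}
    if not needed <= set(df.columns):
        raise MinaError(f"{path}: GWAS table needs columns {sorted(needed)}")
    pvals = df["P"].astype(float).to_numpy()
    if (pvals == 0).any():
        positive = pvals[pvals > 0]
        if positive.size == 0:
            raise MinaError(f"{path}: all p-values are zero")
        floor = float(positive.min())
        warnings.warn(
            f"{path}: {int((pvals == 0).sum())} zero p-values floored at {floor:g}"
        )
        pvals = np.where(pvals == 0, floor, pvals)
    return [
        SnpAssociation(
            snp_id=str(row.SNP), chrom=str(row.CHR), pos=int(row.POS), p_value=p
        )
        for row, p in zip(df.itertuples(index=False), pvals)
    ]


# ---------------------------------------------------------------------
# assignment and summaries
# ---------------------------------------------------------------------

def assign_snps(
    genes: list[GeneRecord],
    snps: list[SnpAssociation],
    window_kb: int = DEFAULT_WINDOW_KB,
) -> dict[str, list[SnpAssociation]]:
    """Assign each SNP to every gene whose window contains it.

    A SNP belongs to a gene when it sits on the same chromosome within
    the gene body extended ``window_kb`` kilobases both ways; a SNP in
    two overlapping windows is assigned to both genes.
    """
    if window_kb < 0:
        raise MinaError("window_kb must be >= 0")
    window_bp = window_kb * 1000
    gene_chroms = {g.chrom for g in genes}
    snp_chroms = {s.chrom for s in snps}
    if genes and snps and not gene_chroms & snp_chroms:
        warnings.warn(
            "no chromosome names shared between genes and SNPs; "
            f"genes use {sorted(gene_chroms)[:3]}..., SNPs {sorted(snp_chroms)[:3]}..."
        )
    by_chrom: dict[str, list[SnpAssociation]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_snps in by_chrom.values():
        chrom_snps.sort(key=lambda s: s.pos)
    positions = {c: np.array([s.pos for s in ss]) for c, ss in by_chrom.items()}

    out: dict[str, list[SnpAssociation]] = {}
    for gene in genes:
        ws, we = gene.window(window_bp)
        hits: list[SnpAssociation] = []
        if gene.chrom in by_chrom:
            pos = positions[gene.chrom]
            lo = int(np.searchsorted(pos, ws, side="left"))
            hi = int(np.searchsorted(pos, we, side="right"))
            hits = by_chrom[gene.chrom][lo:hi]
        out[gene.symbol] = list(hits)
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def count_independent(
    snps: list[SnpAssociation],
    ld: LdTable,
    threshold: float = DEFAULT_DPRIME,
    missing: str = "zero",
) -> tuple[int, dict[str, int]]:
    """Number of independent SNPs by transitive LD clustering.

    SNP pairs with D' at or above the threshold are linked; the clusters
    are the connected components of that LD graph, and the independent
    count is the number of clusters.  Deterministic and invariant to the
    input order.  ``missing`` controls pairs absent from the table:
    ``zero`` assumes no LD, ``error`` raises.
    """
    if not 0.0 <= threshold <= 1.0:
        raise MinaError("D' threshold must be in [0, 1]")
    ids = sorted({s.snp_id for s in snps})
    if not ids:
        return 0, {}
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if ld.get(a, b, missing=missing) >= threshold:
                uf.union(a, b)
    roots = sorted({uf.find(x) for x in ids})
    label = {r: i + 1 for i, r in enumerate(roots)}
    clusters = {x: label[uf.find(x)] for x in ids}
    return len(roots), clusters


@dataclass(frozen=True)
class GeneAssociationSummary:
    """Per-gene association report.

    ``min_p_corrected`` is the per-gene Bonferroni-corrected minimum:
    the smallest p-value multiplied by the gene's independent-SNP count,
    capped at 1.
    """

    symbol: str
    n_snps_total: int
    n_snps_p05: int
    n_independent: int
    min_p_raw: float
    min_p_corrected: float

    @property
    def tested(self) -> bool:
        return self.n_snps_total > 0

    @property
    def significant(self) -> bool:
        return self.tested and self.min_p_corrected < ALPHA


def summarize_gene(
    gene: GeneRecord,
    snps: list[SnpAssociation],
    ld: LdTable,
    threshold: float = DEFAULT_DPRIME,
    missing: str = "zero",
) -> GeneAssociationSummary:
    """Summarise one gene's assigned SNPs with LD-aware Bonferroni.

    A gene with no assigned SNPs is reported untested (zero counts, NaN
    p fields) rather than dropped.
    """
    if not snps:
        return GeneAssociationSummary(
            symbol=gene.symbol,
            n_snps_total=0,
            n_snps_p05=0,
            n_independent=0,
            min_p_raw=float("nan"),
            min_p_corrected=float("nan"),
        )
    n_independent, _ = count_independent(snps, ld, threshold, missing)
    pvals = [s.p_value for s in snps]
    min_raw = min(pvals)
    return GeneAssociationSummary(
        symbol=gene.symbol,
        n_snps_total=len(snps),
        n_snps_p05=sum(1 for p in pvals if p < ALPHA),
        n_independent=n_independent,
        min_p_raw=min_raw,
        min_p_corrected=min(1.0, min_raw * n_independent),
    )


def summarize_genes(
    genes: list[GeneRecord],
    snps: list[SnpAssociation],
    ld: LdTable,
    window_kb: int = DEFAULT_WINDOW_KB,
    threshold: float = DEFAULT_DPRIME,
    missing: str = "zero",
) -> pd.DataFrame:
    """Per-gene association table over a gene list (one row per gene)."""
    assigned = assign_snps(genes, snps, window_kb)
    rows = []
    for gene in genes:
        s = summarize_gene(gene, assigned[gene.symbol], ld, threshold, missing)
        rows.append(
            {
                "symbol": s.symbol,
                "n_snps_total": s.n_snps_total,
                "n_snps_p05": s.n_snps_p05,
                "n_independent": s.n_independent,
                "min_p_raw": s.min_p_raw,
                "min_p_corrected": s.min_p_corrected,
                "significant": s.significant,
            }
        )
    return pd.DataFrame(rows)


def significant_snps(
    genes: list[GeneRecord],
    snps: list[SnpAssociation],
    ld: LdTable,
    window_kb: int = DEFAULT_WINDOW_KB,
    threshold: float = DEFAULT_DPRIME,
) -> pd.DataFrame:
    """SNPs whose per-gene Bonferroni-corrected p clears 0.05.

    These are the candidate SNPs a replication study carries forward;
    one row per (gene, SNP) pair.
    """
    assigned = assign_snps(genes, snps, window_kb)
    rows = []
    for gene in genes:
        gene_snps = assigned[gene.symbol]
        if not gene_snps:
            continue
        n_ind, _ = count_independent(gene_snps, ld, threshold)
        for s in gene_snps:
            corrected = min(1.0, s.p_value * n_ind)
            if corrected < ALPHA:
                rows.append(
                    {
                        "gene": gene.symbol,
                        "snp_id": s.snp_id,
                        "chrom": s.chrom,
                        "pos": s.pos,
                        "p_primary": s.p_value,
                        "p_primary_corrected": corrected,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "snp_id", "chrom", "pos", "p_primary", "p_primary_corrected",
        ],
    )


def replicate(
    candidate_snps: pd.DataFrame,
    second_dataset: list[SnpAssociation],
    ld: LdTable,
    threshold: float = DEFAULT_DPRIME,
) -> pd.DataFrame:
    """Test candidate SNPs in a second dataset.

    The Bonferroni denominator is the number of *independent* candidate
    SNPs carried forward (LD clustering at the same threshold).  Each
    candidate is flagged ``replicated`` when its corrected second-dataset
    p clears 0.05, ``not_replicated`` otherwise, or ``untested`` when the
    SNP is absent from the second dataset.  A gene replicates when any of
    its SNPs does.
    """
    lookup = {s.snp_id: s for s in second_dataset}
    if len(candidate_snps) == 0:
        return pd.DataFrame(
            columns=[
                "gene", "snp_id", "p_replication",
                "p_replication_corrected", "status", "m_independent",
            ]
        )
    unique = (
        candidate_snps[["snp_id", "chrom", "pos"]]
        .drop_duplicates("snp_id")
        .itertuples(index=False)
    )
    carried = [
        SnpAssociation(snp_id=u.snp_id, chrom=str(u.chrom), pos=int(u.pos), p_value=1.0)
        for u in unique
    ]
    m, _ = count_independent(carried, ld, threshold)
    rows = []
    for row in candidate_snps.itertuples(index=False):
        hit = lookup.get(row.snp_id)
        if hit is None:
            rows.append(
                {
                    "gene": row.gene,
                    "snp_id": row.snp_id,
                    "p_replication": float("nan"),
                    "p_replication_corrected": float("nan"),
                    "status": "untested",
                    "m_independent": m,
                }
            )
            continue
        corrected = min(1.0, hit.p_value * m)
        rows.append(
            {
                "gene": row.gene,
                "snp_id": row.snp_id,
                "p_replication": hit.p_value,
                "p_replication_corrected": corrected,
                "status": "replicated" if corrected < ALPHA else "not_replicated",
                "m_independent": m,
            }
        )
    return pd.DataFrame(rows)
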
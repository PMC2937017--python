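"""Copy-number/expression linkage of associated region pairs.

For each gene pair spanning an associated region pair, four Pearson tests
are run: copy number of gene X vs copy number of gene Y, copy number vs
expression within each gene, and expression of X vs expression of Y.  A
pair passes only when all four are significant at the chosen alpha.  This
is a screen, not an inference: no multiplicity correction is applied inside
it, by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CopyNumberProfile, Region


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


def read_genes(path) -> list[Gene]:
    """BED4 gene model: chrom, start, end, gene_id."""
    genes = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            genes.append(
                Gene(fields[3], fields[0], int(fields[1]), int(fields[2]))
            )
    return genes


def gene_level_cn(
    profile: CopyNumberProfile, chrom: str, start: int, end: int
) -> float | None:
    """Length-weighted mean log2 over the segments covering an interval;
    None when nothing overlaps."""
    total = 0
    acc = 0.0
    for seg in profile.by_chrom(chrom):
        if seg.start >= end:
            break
        if seg.end <= start:
            continue
        w = min(seg.end, end) - max(seg.start, start)
        total += w
        acc += w * seg.log2
    if total == 0:
        return None
    return acc / total


def gene_cn_matrix(
    profiles: Sequence[CopyNumberProfile], genes: Sequence[Gene]
) -> pd.DataFrame:
    """Genes-by-samples matrix of gene-level copy-number log2 (NaN = uncovered)."""
    data = np.full((len(genes), len(profiles)), np.nan)
    for gi, gene in enumerate(genes):
        for si, profile in enumerate(profiles):
            cn = gene_level_cn(profile, gene.chrom, gene.start, gene.end)
            if cn is not None:
                data[gi, si] = cn
    return pd.DataFrame(
        data,
        index=[g.gene_id for g in genes],
        columns=[p.sample_id for p in profiles],
    )


def assign_genes(
    genes: Sequence[Gene], regions: Sequence[Region], flank: int = 10_000
) -> dict[str, list[Gene]]:
    """Genes overlapping each region extended by a flank on both sides."""
    out: dict[str, list[Gene]] = {r.label: [] for r in regions}
    for region in regions:
        lo, hi = region.start - flank, region.end + flank
        for gene in genes:
            if gene.chrom == region.chrom and gene.start < hi and lo < gene.end:
                out[region.label].append(gene)
    return out


@dataclass
class LinkResult:
    gene_x: str
    gene_y: str
    region_a: str
    region_b: str
    r_cncn: float
    p_cncn: float
    r_cnex_x: float
    p_cnex_x: float
    r_cnex_y: float
    p_cnex_y: float
    r_exex: float
    p_exex: float
    testable: bool
    passed: bool

    @property
    def min_abs_r(self) -> float:
        return min(
            abs(self.r_cncn), abs(self.r_cnex_x), abs(self.r_cnex_y),
            abs(self.r_exex),
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float] | None:
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        return None
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return None
    r, p = stats.pearsonr(xv, yv)
    return float(r), float(p)


def four_way_link(
    cn: pd.DataFrame,
    expression: pd.DataFrame,
    region_pairs: Sequence[tuple[Region, Region]],
    genes: Sequence[Gene],
    alpha: float = 0.05,
    flank: int = 10_000,
) -> list[LinkResult]:
    """Run the four-test screen for every gene pair spanning each associated
    region pair, on the samples shared by the CN and expression matrices.

    Degenerate inputs (constant vectors, < 3 complete samples) yield
    testable=False rather than a failed test.
    """
    shared = [s for s in cn.columns if s in set(expression.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 samples shared between CN and expression")
    cn = cn[shared]
    expression = expression[shared]
    all_regions: list[Region] = []
    for a, b in region_pairs:
        for r in (a, b):
            if all(r.label != x.label for x in all_regions):
                all_regions.append(r)
    by_region = assign_genes(genes, all_regions, flank=flank)
    results: list[LinkResult] = []
    for region_a, region_b in region_pairs:
        for gene_x in by_region[region_a.label]:
            for gene_y in by_region[region_b.label]:
                if gene_x.gene_id == gene_y.gene_id:
                    continue
                cn_x = cn.loc[gene_x.gene_id].to_numpy(dtype=float)
                cn_y = cn.loc[gene_y.gene_id].to_numpy(dtype=float)
                ex_x = expression.loc[gene_x.gene_id].to_numpy(dtype=float)
                ex_y = expression.loc[gene_y.gene_id].to_numpy(dtype=float)
                tests = [
                    _pearson(cn_x, cn_y),
                    _pearson(cn_x, ex_x),
                    _pearson(cn_y, ex_y),
                    _pearson(ex_x, ex_y),
                ]
                testable = all(t is not None for t in tests)
                if testable:
                    (r1, p1), (r2, p2), (r3, p3), (r4, p4) = tests
                    passed = all(p < alpha for p in (p1, p2, p3, p4))
                else:
                    r1 = p1 = r2 = p2 = r3 = p3 = r4 = p4 = np.nan
                    passed = False
                results.append(
                    LinkResult(
                        gene_x.gene_id, gene_y.gene_id,
                        region_a.label, region_b.label,
                        r1, p1, r2, p2, r3, p3, r4, p4,
                        testable=testable, passed=passed,
                    )
                )
    return results


def links_to_frame(results: Sequence[LinkResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
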
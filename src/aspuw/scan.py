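"""Genome-wide gene scan: CpG-to-gene mapping, per-gene adaptive tests,
multiple-testing adjustment and calibration diagnostics.

The null mixed model is fitted once per phenotype — variance components
do not depend on the gene — and each gene then costs only a score
extraction plus Monte Carlo p-values.  Per-gene seeds are derived from
(master seed, gene_id), so scan results are independent of gene order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import derive_entropy
from .exceptions import ValidationError
from .io import GeneAnnotation, MethylationMatrix, SampleFrame
from .model import FamilyMixedLM
from .relatedness import VarianceComponentSet
from .spuw import DEFAULT_GAMMAS, GammaSet

__all__ = [
    "ScanResult",
    "map_cpgs_to_genes",
    "run_scan",
    "bonferroni_threshold",
    "genomic_lambda",
    "manhattan_table",
]

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """One row per annotated gene plus scan metadata.

    ``table`` columns: gene_id, chrom, start, end, n_cpgs, testable,
    per-gamma statistics and p-values, aspuw_p, B.
    """

    table: pd.DataFrame
    gammas: GammaSet
    weight_mode: str
    seed: int
    alpha: float = 0.05
    metadata: dict = field(default_factory=dict)

    @property
    def n_testable(self) -> int:
        return int(self.table["testable"].sum())

    @property
    def threshold(self) -> float:
        """Bonferroni threshold over testable genes."""
        return bonferroni_threshold(self.alpha, self.n_testable)

    def significant(self) -> pd.DataFrame:
        t = self.table
        return t[t["testable"] & (t["aspuw_p"] < self.threshold)]

    def genomic_lambda(self, column: str = "aspuw_p") -> float:
        p = self.table.loc[self.table["testable"], column].to_numpy(float)
        return genomic_lambda(p)


def map_cpgs_to_genes(
    manifest: pd.DataFrame, genes: list[GeneAnnotation]
) -> dict[str, np.ndarray]:
    """Assign CpGs to genes by position, 0-based half-open [start, end).

    A CpG inside two overlapping genes is assigned to both; genes with
    zero CpGs map to an empty index array (kept, flagged untestable by
    the scan).  Chromosome names must match between the two inputs
    whenever both sides have any annotation on that chromosome family.
    """
    chroms_m = set(map(str, manifest["chrom"].unique()))
    chroms_g = {g.chrom for g in genes}
    if genes and len(manifest) and not (chroms_m & chroms_g):
        raise ValidationError(
            f"no shared chromosome names: manifest has {sorted(chroms_m)[:5]}, "
            f"genes have {sorted(chroms_g)[:5]}"
        )
    pos = manifest["pos"].to_numpy(int)
    chrom = manifest["chrom"].to_numpy(str)
    mapping = {}
    for g in genes:
        mask = (chrom == g.chrom) & (pos >= g.start) & (pos < g.end)
        mapping[g.gene_id] = np.flatnonzero(mask)
    return mapping


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValidationError("n_tests must be a positive count")
    return alpha / n_tests


def genomic_lambda(pvalues) -> float:
    """Genomic-control lambda: median observed chi^2_1 over its null median.

    p-values are converted through the chi-square quantile function with
    1 degree of freedom; lambda ~ 1 indicates calibrated tests, < 1
    conservative ones.
    """
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValidationError("no finite p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))


def manhattan_table(scan: ScanResult, column: str = "aspuw_p") -> pd.DataFrame:
    """Plotting table (gene, chrom, midpoint, -log10 p), untestable
    genes omitted, sorted by chromosome then position."""
    t = scan.table[scan.table["testable"]].copy()
    t["midpoint"] = (t["start"] + t["end"]) / 2.0
    t["neglog10_p"] = -np.log10(t[column].to_numpy(float))
    t = t.sort_values(["chrom", "midpoint"], kind="mergesort")
    return t[["gene_id", "chrom", "midpoint", "neglog10_p"]].reset_index(drop=True)


def run_scan(
    samples: SampleFrame,
    methylation: MethylationMatrix,
    variance_components: VarianceComponentSet,
    genes: list[GeneAnnotation],
    gammas=DEFAULT_GAMMAS,
    B: int = 1000,
    max_b: int | None = None,
    weight: str = "inverse_sd",
    seed: int = 0,
    alpha: float = 0.05,
    fit_kwargs: dict | None = None,
) -> ScanResult:
    """Fit the null model once and test every annotated gene.

    Per-gene failures are recorded in the gene's row (testable = False)
    and never abort the scan.
    """
    gammas = gammas if isinstance(gammas, GammaSet) else GammaSet(tuple(gammas))
    if not np.array_equal(methylation.sample_ids, samples.sample_ids):
        raise ValidationError("methylation matrix not aligned to samples")
    model = FamilyMixedLM.from_frames(samples, variance_components)
    fit = model.fit(**(fit_kwargs or {}))
    logger.info(
        "null model fitted: tau=%s sigma2=%.4f converged=%s",
        np.round(fit.tau, 4), fit.sigma2, fit.converged,
    )
    mapping = map_cpgs_to_genes(methylation.manifest, genes)

    rows = []
    for gene in genes:
        idx = mapping[gene.gene_id]
        row = {
            "gene_id": gene.gene_id,
            "chrom": gene.chrom,
            "start": gene.start,
            "end": gene.end,
            "n_cpgs": int(len(idx)),
            "testable": False,
            "aspuw_p": np.nan,
            "B": 0,
            "error": "",
        }
        for g in gammas:
            key = "inf" if g == math.inf else str(int(g))
            row[f"spuw_{key}_stat"] = np.nan
            row[f"spuw_{key}_p"] = np.nan
        if len(idx) == 0:
            row["error"] = "no CpGs in interval"
            rows.append(row)
            continue
        gene_seed = derive_entropy(seed, "gene", gene.gene_id)
        # collapse the entropy list to one integer stream key per gene
        gene_seed_int = int(
            np.random.SeedSequence(gene_seed).generate_state(1, np.uint32)[0]
        )
        try:
            sub = methylation.subset(idx)
            result = fit.aspuw(
                sub, gammas=gammas, B=B, max_b=max_b, weight=weight,
                seed=gene_seed_int,
            )
        except Exception as err:  # record, never abort the scan
            logger.warning("gene %s failed: %s", gene.gene_id, err)
            row["error"] = str(err)
            rows.append(row)
            continue
        if result.untestable:
            row["error"] = "no CpG with positive variance"
            rows.append(row)
            continue
        row.update(result.to_row())
        row["testable"] = True
        row["n_cpgs"] = int(result.extra.get("n_cpgs", len(idx)))
        rows.append(row)
        logger.debug("gene %s: %d CpGs, aSPUw p = %.3g",
                     gene.gene_id, row["n_cpgs"], row["aspuw_p"])

    table = pd.DataFrame(rows)
    if len(table) == 0 or not table["testable"].any():
        logger.warning("scan produced no testable genes")
    result = ScanResult(
        table=table, gammas=gammas, weight_mode=weight, seed=seed, alpha=alpha,
        metadata={"B": B, "max_b": max_b, "n_genes": len(genes)},
    )
    if result.n_testable:
        result.metadata["bonferroni_threshold"] = result.threshold
    return result
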
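"""Chromosome-wise relative expression and expression-based trisomy calling.

The core statistic is, per sample, the sum of all reads from one chromosome
divided by the sum of all reads from all (annotated) chromosomes.  A
chromosome present in three copies with no dosage compensation raises its
relative expression by a factor

    lambda / (1 + (lambda - 1) * f)

where lambda = 3/2 is the per-copy scaling and f the chromosome's baseline
share of the transcriptome — slightly under 1.5 because the extra reads also
inflate the denominator.  Significance is assessed with a paired t-test
across the genes of the chromosome (candidate-line value vs. reference mean
per gene, on log2(rpm + 1)), Benjamini-Hochberg-adjusted across chromosomes
within each line, and a gain is called when the fraction ratio and the
adjusted p-value both clear their thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneAnnotation, ValidationError
from .normalize import cpm, log_transform


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def relative_chromosome_expression(counts: CountMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-sample chromosome fractions of the assigned-gene read total.

    Genes without a chromosome assignment are excluded from both numerator
    and denominator, so each sample's fractions sum to exactly 1.
    """
    assigned = annotation.assigned(counts.genes)
    if len(assigned) == 0:
        raise ValidationError("annotation shares no genes with the count matrix")
    sub = counts.counts.loc[assigned]
    totals = sub.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"sample(s) with zero assigned reads: {zero}")
    by_chrom = sub.groupby(annotation.chromosome.loc[assigned]).sum()
    frac = (by_chrom / totals).T  # samples x chromosomes
    frac.index.name = "sample"
    frac.columns.name = "chromosome"
    return frac


def line_relative_expression(counts: CountMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Chromosome fractions averaged over the replicates of each line."""
    frac = relative_chromosome_expression(counts, annotation)
    lines = counts.sample_meta.loc[frac.index, "line"]
    out = frac.groupby(lines).mean()
    out.index.name = "line"
    return out.loc[[ln for ln in counts.lines if ln in out.index]]


def dosage_test(counts: CountMatrix, annotation: GeneAnnotation, candidate_line: str,
                reference_lines, chromosome: str, min_genes: int = 3) -> tuple[float, float]:
    """Paired t-test for elevated expression of one chromosome in one line.

    Pairing unit: genes on the chromosome.  For each gene, the candidate
    value is the mean over the candidate line's replicates of log2(rpm + 1);
    the reference value is the mean over all reference-line replicates.
    Returns the two-sided (t, p).
    """
    reference_lines = list(reference_lines)
    if not reference_lines:
        raise ValidationError("dosage_test needs at least one reference line")
    genes = annotation.genes_on(chromosome).intersection(counts.genes)
    cand_samples = counts.samples_of(candidate_line)
    ref_samples = [s for line in reference_lines for s in counts.samples_of(line)]
    involved = cand_samples + ref_samples
    usable = genes[counts.counts.loc[genes, involved].sum(axis=1) > 0]
    if len(usable) < min_genes:
        raise ValidationError(
            f"chromosome {chromosome}: only {len(usable)} genes with nonzero counts "
            f"(need >= {min_genes}); paired test undefined"
        )
    log_rpm = log_transform(cpm(counts.subset_samples(involved))).values.loc[usable]
    cand = log_rpm[cand_samples].mean(axis=1)
    ref = log_rpm[ref_samples].mean(axis=1)
    return _paired_t(cand.to_numpy(), ref.to_numpy())


def _paired_t(cand: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    diff = cand - ref
    if np.allclose(diff, 0.0):
        return 0.0, 1.0  # self-comparison / identical data
    t, p = sps.ttest_rel(cand, ref)
    return float(t), float(p)


@dataclass
class DosageParams:
    ratio_threshold: float = 1.3
    fdr_threshold: float = 0.01
    call_losses: bool = False


class ChromosomeDosageResults:
    """Fitted chromosome-dosage estimates, tests and gain calls.

    Attributes
    ----------
    frame
        One row per (line, chromosome): relative fraction, reference fraction,
        ratio, paired t, p, BH-adjusted p (within line), and the call.
    sample_fractions
        Per-sample chromosome fractions underlying the line averages.
    """

    def __init__(self, model: "ChromosomeDosageModel", frame: pd.DataFrame,
                 sample_fractions: pd.DataFrame, params: DosageParams):
        self.model = model
        self.frame = frame
        self.sample_fractions = sample_fractions
        self.params = params

    @property
    def gain_calls(self) -> list[tuple[str, str]]:
        gains = self.frame[self.frame["call"] == "gain"]
        return list(zip(gains["line"], gains["chromosome"]))

    @property
    def lines_with_gains(self) -> list[str]:
        return sorted({line for line, _ in self.gain_calls})

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = [
            "Chromosome dosage analysis",
            f"  lines: {', '.join(self.model.lines)}",
            f"  reference: {self.model.reference} ({self.model.reference_stat} of reference lines)",
            f"  call rule: ratio >= {self.params.ratio_threshold} and "
            f"BH-adjusted p <= {self.params.fdr_threshold}",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", None):
            lines.append(self.frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        calls = self.gain_calls
        lines.append("")
        if calls:
            lines.append("Gains called: " + ", ".join(f"{ln}:chr{c}" for ln, c in calls))
        else:
            lines.append("Gains called: none")
        return "\n".join(lines)


class ChromosomeDosageModel:
    """Expression-based karyotyping of a cohort of cell lines.

    Parameters
    ----------
    counts, annotation
        The count matrix and gene-to-chromosome assignment.
    lines
        Lines to analyse (default: all lines in the matrix).
    reference
        ``"leave-one-out"`` (each line is compared against all other analysed
        lines) or ``"explicit"`` with ``reference_lines``.
    reference_stat
        Aggregation of reference-line fractions: ``"median"`` (default,
        robust to an aneuploid line inside the reference set) or ``"mean"``.
    include_x, include_y
        Whether the sex chromosomes take part in trisomy calling.  Both are
        excluded by default: their dosage is confounded by sex and
        X-inactivation state and is handled by the X-status model.
    """

    def __init__(self, counts: CountMatrix, annotation: GeneAnnotation, *,
                 lines=None, reference: str = "leave-one-out", reference_lines=None,
                 reference_stat: str = "median", include_x: bool = False,
                 include_y: bool = False):
        self.counts = counts
        self.annotation = annotation
        self.lines = list(lines) if lines is not None else counts.lines
        if reference_lines is not None:
            reference = "explicit"
        if reference == "explicit" and not reference_lines:
            raise ValidationError("explicit reference requires reference_lines")
        if reference not in ("leave-one-out", "explicit"):
            raise ValidationError(f"unknown reference mode {reference!r}")
        self.reference = reference
        self.reference_lines = list(reference_lines) if reference_lines else None
        if reference_stat not in ("median", "mean"):
            raise ValidationError("reference_stat must be 'median' or 'mean'")
        self.reference_stat = reference_stat
        self.include_x = include_x
        self.include_y = include_y

    def calling_chromosomes(self) -> list[str]:
        chroms = [c for c in self.annotation.chromosomes]
        if not self.include_y:
            chroms = [c for c in chroms if c != "Y"]
        if not self.include_x:
            chroms = [c for c in chroms if c != "X"]
        return chroms

    def _reference_for(self, line: str) -> list[str]:
        if self.reference == "explicit":
            return [ln for ln in self.reference_lines if ln != line]
        return [ln for ln in self.lines if ln != line]

    def fit(self, ratio_threshold: float = 1.3, fdr_threshold: float = 0.01,
            call_losses: bool = False) -> ChromosomeDosageResults:
        params = DosageParams(ratio_threshold, fdr_threshold, call_losses)
        involved = list(dict.fromkeys(self.lines + (self.reference_lines or [])))
        sub = self.counts.subset_lines(involved)
        sample_fractions = relative_chromosome_expression(sub, self.annotation)
        line_frac = line_relative_expression(sub, self.annotation)
        chroms = self.calling_chromosomes()

        # Shared per-gene log2(rpm+1) means; dosage_test recomputes the same
        # values — this just avoids renormalizing once per (line, chromosome).
        log_rpm = log_transform(cpm(sub)).values
        line_gene_means = {
            line: log_rpm[sub.samples_of(line)].mean(axis=1) for line in involved
        }
        chrom_genes = {
            c: self.annotation.genes_on(c).intersection(sub.genes) for c in chroms
        }

        rows = []
        for line in self.lines:
            refs = self._reference_for(line)
            if not refs:
                raise ValidationError(f"no reference lines available for {line!r}")
            agg = getattr(line_frac.loc[refs], self.reference_stat)(axis=0)
            ref_samples = [s for r in refs for s in sub.samples_of(r)]
            ref_gene_mean = log_rpm[ref_samples].mean(axis=1)
            gene_totals = sub.counts[sub.samples_of(line) + ref_samples].sum(axis=1)
            pvals, trow = [], []
            for chrom in chroms:
                genes = chrom_genes[chrom]
                usable = genes[gene_totals.loc[genes] > 0]
                if len(usable) < 3:
                    raise ValidationError(
                        f"chromosome {chrom}: only {len(usable)} genes with nonzero "
                        "counts (need >= 3); paired test undefined"
                    )
                t, p = _paired_t(
                    line_gene_means[line].loc[usable].to_numpy(),
                    ref_gene_mean.loc[usable].to_numpy(),
                )
                trow.append(t)
                pvals.append(p)
            padj = benjamini_hochberg(pvals)
            for chrom, t, p, pa in zip(chroms, trow, pvals, padj):
                frac = line_frac.loc[line, chrom]
                ref_frac = agg[chrom]
                ratio = frac / ref_frac
                call = "normal"
                if ratio >= ratio_threshold and pa <= fdr_threshold:
                    call = "gain"
                elif call_losses and ratio <= 1.0 / ratio_threshold and pa <= fdr_threshold:
                    call = "loss"
                rows.append((line, chrom, frac, ref_frac, ratio, t, p, pa, call))

        frame = pd.DataFrame(
            rows,
            columns=["line", "chromosome", "fraction", "reference_fraction",
                     "ratio", "t", "p", "p_adj", "call"],
        )
        return ChromosomeDosageResults(self, frame, sample_fractions, params)
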
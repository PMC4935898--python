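"""X-linked dosage, XIST abundance and X-inactivation classification.

Female cells silence one X chromosome through the long non-coding RNA XIST;
female lines that fail to do so show roughly double the X-linked output of a
single active X (observed folds run below 2 because of escape genes) and
essentially no XIST.  Three quantities per line drive the classification:

* ``x_avg_rpm`` — mean reads per million per X-linked gene (XIST excluded,
  since it marks the *inactive* X and would distort the dosage average);
* ``xist_rpm`` — XIST reads per million;
* ``y_rpm_total`` — summed Y-linked rpm, used to call sex when metadata is
  silent.

Classes: ``male_single_X``; ``female_XIST_pos_Xi`` (XIST-positive, one X
inactivated); ``female_XIST_neg_biactive`` (XIST-negative with elevated
X dosage); anything else is flagged ``ambiguous``.  The default thresholds
(XIST >= 100 rpm for positive, <= 10 rpm for negative, X fold >= 1.3) sit an
order of magnitude away from observed values on either side, so calls are
insensitive to large threshold shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosage import dosage_test
from .io import CountMatrix, GeneAnnotation, ValidationError
from .normalize import cpm

MALE_SINGLE_X = "male_single_X"
FEMALE_XIST_POS = "female_XIST_pos_Xi"
FEMALE_BIACTIVE = "female_XIST_neg_biactive"
AMBIGUOUS = "ambiguous"


def _line_mean_rpm(counts: CountMatrix, genes, line: str) -> pd.Series:
    """Per-gene rpm averaged over a line's replicates."""
    rpm = cpm(counts).values.loc[genes]
    return rpm[counts.samples_of(line)].mean(axis=1)


def x_average_expression(counts: CountMatrix, annotation: GeneAnnotation, line: str) -> float:
    """Mean rpm per X-linked gene (XIST excluded), replicate-averaged."""
    genes = annotation.x_genes(exclude_xist=True).intersection(counts.genes)
    if len(genes) == 0:
        raise ValidationError("no X-linked genes shared between annotation and counts")
    return float(_line_mean_rpm(counts, genes, line).mean())


def xist_rpm(counts: CountMatrix, annotation: GeneAnnotation, line: str) -> float:
    """XIST reads per million, replicate-averaged."""
    xist = annotation.require_xist()
    if xist not in counts.genes:
        raise ValidationError(f"XIST gene {xist!r} absent from the count matrix")
    return float(_line_mean_rpm(counts, pd.Index([xist]), line).iloc[0])


def y_rpm_total(counts: CountMatrix, annotation: GeneAnnotation, line: str) -> float:
    """Summed rpm over Y-linked genes, replicate-averaged (0 if no Y genes)."""
    genes = annotation.genes_on("Y").intersection(counts.genes)
    if len(genes) == 0:
        return 0.0
    return float(_line_mean_rpm(counts, genes, line).sum())


@dataclass
class XThresholds:
    xist_high: float = 100.0  # rpm at/above which a line counts as XIST-positive
    xist_low: float = 10.0  # rpm at/below which a line counts as XIST-negative
    x_fold_threshold: float = 1.3  # X dosage fold marking a biactive X
    y_rpm_threshold: float = 1.0  # summed Y rpm above which a line is male

    def __post_init__(self):
        if self.xist_low >= self.xist_high:
            raise ValidationError("xist_low must be strictly below xist_high")


def classify_x_state(sex: str, xist: float, x_fold: float, thresholds: XThresholds) -> str:
    if sex == "male":
        return MALE_SINGLE_X
    if xist >= thresholds.xist_high:
        return FEMALE_XIST_POS
    if xist <= thresholds.xist_low and x_fold >= thresholds.x_fold_threshold:
        return FEMALE_BIACTIVE
    return AMBIGUOUS


class XStatusResults:
    """Per-line X dosage, XIST abundance, sex call and X-inactivation class."""

    def __init__(self, model: "XStatusModel", frame: pd.DataFrame, thresholds: XThresholds):
        self.model = model
        self.frame = frame
        self.thresholds = thresholds

    def x_class_of(self, line: str) -> str:
        return self.frame.loc[line, "x_class"]

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="line", float_format="%.6g")

    def summary(self) -> str:
        th = self.thresholds
        out = [
            "X-inactivation status",
            f"  thresholds: XIST-positive >= {th.xist_high} rpm, XIST-negative <= {th.xist_low} rpm, "
            f"X fold >= {th.x_fold_threshold}, male if Y rpm >= {th.y_rpm_threshold}",
            "",
            self.frame.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(out)


class XStatusModel:
    """Classify sex and X-inactivation state for each line of a cohort.

    Sex comes from sample metadata (``reported_sex``) when present and from
    Y-linked expression otherwise; set ``use_reported_sex=False`` to force
    the expression-based call.  ``x_fold_vs_cohort`` compares each line's
    X-linked average rpm with the mean of the other lines.
    """

    def __init__(self, counts: CountMatrix, annotation: GeneAnnotation, *,
                 lines=None, use_reported_sex: bool = True):
        self.counts = counts
        self.annotation = annotation
        self.lines = list(lines) if lines is not None else counts.lines
        self.use_reported_sex = use_reported_sex
        if len(self.lines) < 2:
            raise ValidationError("x_fold_vs_cohort needs at least two lines")

    def _reported_sex(self, line: str) -> str | None:
        meta = self.counts.sample_meta
        if "reported_sex" not in meta.columns:
            return None
        vals = meta.loc[self.counts.samples_of(line), "reported_sex"].dropna().unique()
        return str(vals[0]) if len(vals) else None

    def fit(self, thresholds: XThresholds | None = None, **kwargs) -> XStatusResults:
        thresholds = thresholds or XThresholds(**kwargs)
        sub = self.counts.subset_lines(self.lines)
        x_avg = {ln: x_average_expression(sub, self.annotation, ln) for ln in self.lines}
        rows = []
        for line in self.lines:
            xist = xist_rpm(sub, self.annotation, line)
            y_total = y_rpm_total(sub, self.annotation, line)
            others = [ln for ln in self.lines if ln != line]
            x_fold = x_avg[line] / float(np.mean([x_avg[ln] for ln in others]))
            sex = self._reported_sex(line) if self.use_reported_sex else None
            if sex is None:
                sex = "male" if y_total >= thresholds.y_rpm_threshold else "female"
            x_class = classify_x_state(sex, xist, x_fold, thresholds)
            try:
                _, x_p = dosage_test(sub, self.annotation, line, others, "X")
            except ValidationError:
                x_p = float("nan")  # too few usable X genes for the paired test
            rows.append((line, x_avg[line], xist, y_total, sex, x_fold, x_p, x_class))
        frame = pd.DataFrame(
            rows,
            columns=["line", "x_avg_rpm", "xist_rpm", "y_rpm_total", "sex_call",
                     "x_fold_vs_cohort", "x_p_value", "x_class"],
        ).set_index("line")
        return XStatusResults(self, frame, thresholds)
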
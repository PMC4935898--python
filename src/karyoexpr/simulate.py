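"""Synthetic bulk RNA-seq cohorts with known karyotype and X-inactivation truth.

The generative model is deliberately simple: each gene has a per-copy mean
expression (reads per library per gene copy at reference depth), and a
sample's expected count is that mean times the effective number of expressed
copies, with negative-binomial sampling noise on top (variance mu + alpha*mu^2).
Autosomal trisomies therefore raise their chromosome's output by a factor 1.5
with no dosage compensation, which is the regime the dosage caller is built to
detect.  X-linked dosage is modelled through effective copies:

* male: 1 expressed copy;
* female with two active X's: 2 copies;
* female with an inactive X: 1 + escape_fraction copies for ordinary X genes
  (escape_fraction is the average extra output leaking from the inactive X)
  and 2 copies for genes flagged as full escapees.

XIST is a single dedicated X gene whose abundance is injected directly as an
expected reads-per-million target (it does not follow copy-number scaling:
it is expressed *from* the inactive X).  Y genes are silent in females.

On top of the copy-number signal, two nuisance layers make the cohort
realistic enough to exercise normalization and clustering: a per-replicate
sequencing-depth jitter (log-normal, sigma 0.1) and a per-line per-gene
expression individuality (log-normal, sigma 0.2) shared by the replicates of
a line — cell lines genuinely differ gene-by-gene, replicates of one line do
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, ValidationError

MALE, FEMALE = "male", "female"
NOT_APPLICABLE = "not_applicable"
ACTIVE_ACTIVE = "active_active"
INACTIVE_WITH_ESCAPE = "inactive_with_escape"
X_STATES = (NOT_APPLICABLE, ACTIVE_ACTIVE, INACTIVE_WITH_ESCAPE)

PLURIPOTENCY_MARKERS = (
    "POU5F1", "SOX2", "NANOG", "LIN28A", "KLF4", "KLF5", "UTF1", "DPPA3", "GDF3", "TERT",
)
NAIVE_PRIMED_MARKERS = ("ZFP42", "NR0B1", "FGF4", "FGF5", "T")


@dataclass(frozen=True)
class GeneModel:
    """Generative parameters for one gene."""

    gene_id: str
    chromosome: str
    per_copy_mean: float  # expected reads per library per gene copy at reference depth
    dispersion: float  # NB alpha, variance = mu + alpha * mu^2
    is_xist: bool = False
    x_escape: bool = False

    def __post_init__(self):
        if self.per_copy_mean < 0:
            raise ValidationError(f"{self.gene_id}: per_copy_mean must be >= 0")
        if self.dispersion < 0:
            raise ValidationError(f"{self.gene_id}: dispersion must be >= 0")
        if self.x_escape and self.chromosome != "X":
            raise ValidationError(f"{self.gene_id}: x_escape only applies to X-linked genes")


@dataclass
class KaryotypeSpec:
    """Ground-truth karyotype and X state for one cell line.

    ``copy_number`` lists deviations from the default (2 for autosomes; X and
    Y are filled in from ``sex``).  ``expression_multipliers`` optionally
    rescales individual genes' expected expression — used to give the
    fibroblast outgroup its own transcriptional identity and to plant
    differential-expression effects; it is not part of the karyotype truth.
    """

    sample_id: str
    sex: str
    x_state: str | None = None
    copy_number: dict[str, int] = field(default_factory=dict)
    escape_fraction: float = 0.4
    xist_rpm_target: float = 0.0
    cell_type: str = "es"
    expression_multipliers: dict[str, float] | None = None

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE):
            raise ValidationError(f"{self.sample_id}: sex must be male or female")
        if self.x_state is None:
            self.x_state = NOT_APPLICABLE if self.sex == MALE else INACTIVE_WITH_ESCAPE
        if self.x_state not in X_STATES:
            raise ValidationError(f"{self.sample_id}: unknown x_state {self.x_state!r}")
        if self.sex == MALE:
            if self.x_state != NOT_APPLICABLE:
                raise ValidationError(f"{self.sample_id}: male lines take x_state=not_applicable")
            if self.copy_number.get("X", 1) != 1:
                raise ValidationError(f"{self.sample_id}: male lines carry one X")
            if self.xist_rpm_target > 3.0:
                raise ValidationError(
                    f"{self.sample_id}: male XIST target must stay at background (<= 3 rpm)"
                )
        else:
            if self.x_state == NOT_APPLICABLE:
                raise ValidationError(f"{self.sample_id}: female lines need an x_state")
            if self.x_state == ACTIVE_ACTIVE and self.xist_rpm_target > 10.0:
                raise ValidationError(
                    f"{self.sample_id}: biactive-X lines are XIST-negative by definition"
                )
            if self.x_state == INACTIVE_WITH_ESCAPE and self.xist_rpm_target <= 0:
                raise ValidationError(
                    f"{self.sample_id}: an XIST-silenced inactive X is inconsistent; "
                    "give xist_rpm_target > 0 or x_state=active_active"
                )
        if not 0.0 <= self.escape_fraction <= 1.0:
            raise ValidationError(f"{self.sample_id}: escape_fraction must lie in [0, 1]")
        if self.xist_rpm_target < 0:
            raise ValidationError(f"{self.sample_id}: xist_rpm_target must be >= 0")
        for chrom, cn in self.copy_number.items():
            if not (isinstance(cn, (int, np.integer)) and cn >= 0):
                raise ValidationError(
                    f"{self.sample_id}: copy number for {chrom} must be a non-negative integer, got {cn!r}"
                )

    def effective_copies(self, gene: GeneModel) -> float:
        """Expressed copy number for ``gene`` under this karyotype."""
        c = gene.chromosome
        if gene.is_xist:
            return 0.0  # XIST abundance is injected from xist_rpm_target
        if c == "Y":
            return float(self.copy_number.get("Y", 1)) if self.sex == MALE else 0.0
        if c == "X":
            if self.sex == MALE:
                return float(self.copy_number.get("X", 1))
            if self.x_state == ACTIVE_ACTIVE:
                return 2.0
            return 2.0 if gene.x_escape else 1.0 + self.escape_fraction
        return float(self.copy_number.get(c, 2))


@dataclass
class SimulationConfig:
    """Cohort-level generator settings.

    Defaults give a desk-scale cohort patterned on the study design: 20
    autosomes of 250 genes — except the two smallest, 19 and 20, at 150 genes
    so each carries ~3% of total expression — plus X (250 genes, one of them
    XIST) and Y (20 genes); 2e6 expected reads per replicate and 2 biological
    replicates per line.
    """

    n_genes: dict[str, int]
    library_size: float = 2e6
    n_replicates: int = 2
    dispersion: float = 0.02
    depth_sigma: float = 0.1
    line_effect_sigma: float = 0.1
    log_mean_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValidationError("library_size must be > 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.dispersion < 0 or self.depth_sigma < 0 or self.line_effect_sigma < 0:
            raise ValidationError("dispersion and jitter sigmas must be >= 0")
        for chrom, n in self.n_genes.items():
            if n < 1:
                raise ValidationError(f"chromosome {chrom}: n_genes must be >= 1")

    @property
    def chromosomes(self) -> list[str]:
        return list(self.n_genes)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    n_genes = {str(i): 250 for i in range(1, 19)}
    n_genes["19"] = 150
    n_genes["20"] = 150
    n_genes["X"] = 250
    n_genes["Y"] = 20
    return SimulationConfig(n_genes=n_genes, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Gene model construction


def build_gene_model(config: SimulationConfig, rng: np.random.Generator | None = None) -> list[GeneModel]:
    """Draw per-gene per-copy means and assemble the cohort's gene model.

    Per-copy means follow a heavy-tailed log-normal (sigma
    ``config.log_mean_sigma``) and are rescaled so that the expected disomic
    library (two copies of every non-Y gene) totals ``config.library_size``.
    If chromosome X is present, exactly one X gene is the XIST locus with
    per-copy mean 0 — its output is injected from each karyotype's
    ``xist_rpm_target``.
    """
    rng = rng or np.random.default_rng(config.seed)
    gene_ids, chroms = [], []
    for chrom, n in config.n_genes.items():
        for i in range(n):
            gene_ids.append(f"CJ{chrom}G{i + 1:04d}")
            chroms.append(chrom)
    chroms = np.asarray(chroms)
    means = rng.lognormal(mean=0.0, sigma=config.log_mean_sigma, size=len(gene_ids))

    xist_index = None
    if "X" in config.n_genes:
        xist_index = int(np.flatnonzero(chroms == "X")[0])
        gene_ids[xist_index] = "XIST"
        means[xist_index] = 0.0

    non_y = chroms != "Y"
    means = means * (config.library_size / (2.0 * means[non_y].sum()))

    return [
        GeneModel(
            gene_id=g,
            chromosome=c,
            per_copy_mean=float(m),
            dispersion=config.dispersion,
            is_xist=(i == xist_index),
        )
        for i, (g, c, m) in enumerate(zip(gene_ids, chroms, means))
    ]


def assign_marker_genes(models: list[GeneModel]) -> tuple[list[GeneModel], dict[str, list[str]]]:
    """Rename one gene on each of the first autosomes to a named marker gene.

    Returns the updated models and marker panels (``pluripotency``,
    ``naive_primed``) for the annotation.  Marker identity only matters for
    reporting; their generative parameters are untouched.
    """
    markers = list(PLURIPOTENCY_MARKERS) + list(NAIVE_PRIMED_MARKERS)
    by_chrom: dict[str, list[int]] = {}
    for i, m in enumerate(models):
        by_chrom.setdefault(m.chromosome, []).append(i)
    autosomes = [c for c in by_chrom if c not in ("X", "Y")]
    if len(autosomes) < len(markers):
        raise ValidationError(f"need >= {len(markers)} autosomes to place the marker panels")
    models = list(models)
    for name, chrom in zip(markers, autosomes):
        idx = by_chrom[chrom][1]  # not the first gene: keep ids stable elsewhere
        models[idx] = replace(models[idx], gene_id=name)
    panels = {
        "pluripotency": list(PLURIPOTENCY_MARKERS),
        "naive_primed": list(NAIVE_PRIMED_MARKERS),
    }
    return models, panels


def annotation_from_models(models: list[GeneModel],
                           marker_panels: dict[str, list[str]] | None = None) -> GeneAnnotation:
    """Build a GeneAnnotation (with synthetic coordinates) from gene models."""
    chrom = pd.Series(
        [m.chromosome for m in models],
        index=pd.Index([m.gene_id for m in models], name="gene_id"),
    )
    offsets: dict[str, int] = {}
    starts = []
    for m in models:
        pos = offsets.get(m.chromosome, 0)
        starts.append(pos * 2000 + 1)
        offsets[m.chromosome] = pos + 1
    coords = pd.DataFrame(
        {"start": starts, "end": [s + 999 for s in starts], "strand": "+"}, index=chrom.index
    )
    xist = "XIST" if any(m.is_xist for m in models) else None
    return GeneAnnotation(chrom, coords=coords, xist_gene=xist, marker_panels=marker_panels or {})


# ---------------------------------------------------------------------------
# Count simulation


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; alpha = 0 degrades to Poisson."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    lam = mu.copy()
    pos = alpha > 0
    if pos.any():
        lam[pos] = rng.gamma(1.0 / alpha[pos], alpha[pos] * mu[pos])
    return rng.poisson(lam)


def simulate_counts(models: list[GeneModel], karyotypes: list[KaryotypeSpec],
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate NB counts for every line and replicate; return counts + truth.

    Expected count for gene g in replicate r of line s:
    ``per_copy_mean_g * effective_copies(g, s) * line_effect(g, s) * depth_r``
    with NB noise of dispersion alpha.  The XIST gene instead gets
    ``xist_rpm_target * library_size / 1e6 * depth_r``.
    """
    rng = rng or np.random.default_rng(config.seed)
    model_chroms = {m.chromosome for m in models}
    for k in karyotypes:
        missing = [c for c in k.copy_number if c not in model_chroms]
        if missing:
            raise ValidationError(f"{k.sample_id}: karyotype references unknown chromosome(s) {missing}")
        if k.sex == FEMALE and "X" not in model_chroms:
            raise ValidationError(f"{k.sample_id}: female karyotype but no X chromosome in the gene model")
    ids = [m.gene_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids in gene models")
    per_copy = np.array([m.per_copy_mean for m in models])
    alpha = np.array([m.dispersion for m in models])
    is_xist = np.array([m.is_xist for m in models])

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for k in karyotypes:
        copies = np.array([k.effective_copies(m) for m in models])
        base_mu = per_copy * copies
        sigma = config.line_effect_sigma
        line_effect = rng.lognormal(-0.5 * sigma**2, sigma, size=len(models)) if sigma > 0 else 1.0
        base_mu = base_mu * line_effect
        if k.expression_multipliers:
            mult = np.array([k.expression_multipliers.get(g, 1.0) for g in ids])
            if (mult < 0).any():
                raise ValidationError(f"{k.sample_id}: expression multipliers must be >= 0")
            base_mu = base_mu * mult
        if is_xist.any():
            # XIST abundance is a controlled karyotype parameter: injected as an
            # exact expectation, untouched by line-level expression jitter
            base_mu[is_xist] = k.xist_rpm_target * config.library_size / 1e6
        for r in range(1, config.n_replicates + 1):
            ds = config.depth_sigma
            depth = rng.lognormal(-0.5 * ds**2, ds) if ds > 0 else 1.0
            sample = f"{k.sample_id}_r{r}"
            columns[sample] = _nb_draw(rng, base_mu * depth, alpha)
            meta_rows.append((sample, k.sample_id, r, k.sex, k.cell_type))

    counts = pd.DataFrame(columns, index=pd.Index(ids, name="gene_id"), dtype=np.int64)
    meta = pd.DataFrame(
        meta_rows, columns=["sample", "line", "replicate", "reported_sex", "cell_type"]
    ).set_index("sample")
    truth = truth_frame(karyotypes, config.chromosomes)
    return CountMatrix(counts, meta), truth


# ---------------------------------------------------------------------------
# Truth table


def truth_frame(karyotypes: list[KaryotypeSpec], chromosomes: list[str]) -> pd.DataFrame:
    """Ground-truth table: one row per line, karyotype fields + per-chromosome copy number."""
    rows = []
    for k in karyotypes:
        row = {
            "line": k.sample_id,
            "sex": k.sex,
            "x_state": k.x_state,
            "escape_fraction": k.escape_fraction,
            "xist_rpm_target": k.xist_rpm_target,
            "cell_type": k.cell_type,
        }
        for c in chromosomes:
            if c == "X":
                default = 1 if k.sex == MALE else 2
            elif c == "Y":
                default = 1 if k.sex == MALE else 0
            else:
                default = 2
            row[f"cn_{c}"] = k.copy_number.get(c, default)
        rows.append(row)
    return pd.DataFrame(rows).set_index("line")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="line")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="line")


def karyotypes_from_truth(truth: pd.DataFrame) -> list[KaryotypeSpec]:
    """Rebuild KaryotypeSpec objects from a truth table (lossless round trip)."""
    specs = []
    for line, row in truth.iterrows():
        cn = {}
        for col in truth.columns:
            if not col.startswith("cn_"):
                continue
            chrom = col[3:]
            default = 2
            if chrom == "X":
                default = 1 if row["sex"] == MALE else 2
            elif chrom == "Y":
                default = 1 if row["sex"] == MALE else 0
            if int(row[col]) != default:
                cn[chrom] = int(row[col])
        specs.append(
            KaryotypeSpec(
                sample_id=str(line),
                sex=row["sex"],
                x_state=row["x_state"],
                copy_number=cn,
                escape_fraction=float(row["escape_fraction"]),
                xist_rpm_target=float(row["xist_rpm_target"]),
                cell_type=row.get("cell_type", "es"),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Study scenarios


XIST_FEMALE_HIGH = 945.0  # Xi female line, robust XIST expression
XIST_FEMALE_HIGH_2 = 851.0  # second Xi female line
XIST_FEMALE_BIACTIVE = 2.0  # XIST-negative biactive-X female background
XIST_MALE_BACKGROUND = 0.5  # male background transcription, well under 3 rpm


def study_design_karyotypes(include_fibroblast: bool = True) -> list[KaryotypeSpec]:
    """The five-line ES cohort: one male double trisomy (19+20), one Xi female
    single trisomy (20), one euploid Xi female, one euploid male, and one
    euploid biactive-X XIST-negative female — optionally plus a female
    fibroblast outgroup with its own expression profile.
    """
    specs = [
        KaryotypeSpec("ESC1", MALE, copy_number={"19": 3, "20": 3},
                      xist_rpm_target=XIST_MALE_BACKGROUND),
        KaryotypeSpec("ESC2", FEMALE, INACTIVE_WITH_ESCAPE, copy_number={"20": 3},
                      xist_rpm_target=XIST_FEMALE_HIGH),
        KaryotypeSpec("ESC3", FEMALE, INACTIVE_WITH_ESCAPE, xist_rpm_target=XIST_FEMALE_HIGH_2),
        KaryotypeSpec("ESC4", MALE, xist_rpm_target=XIST_MALE_BACKGROUND),
        KaryotypeSpec("ES_REF", FEMALE, ACTIVE_ACTIVE, xist_rpm_target=XIST_FEMALE_BIACTIVE),
    ]
    if include_fibroblast:
        mult: dict[str, float] = {}
        # pluripotency programme off, FGF5 on, ZFP42 unchanged, plus broad
        # lineage-specific rewiring of the rest of the transcriptome
        for g in PLURIPOTENCY_MARKERS + ("NR0B1", "FGF4", "T"):
            mult[g] = 0.0
        mult["FGF5"] = 4.0
        mult["ZFP42"] = 1.0
        mult["__global_sigma__"] = 1.0  # expanded to per-gene draws at simulate time
        specs.append(
            KaryotypeSpec("FIB", FEMALE, INACTIVE_WITH_ESCAPE, xist_rpm_target=300.0,
                          cell_type="fibroblast", expression_multipliers=mult)
        )
    return specs


def _expand_global_multipliers(specs: list[KaryotypeSpec], models: list[GeneModel],
                               rng: np.random.Generator) -> list[KaryotypeSpec]:
    """Replace the ``__global_sigma__`` placeholder by per-gene log-normal multipliers."""
    out = []
    for k in specs:
        mult = dict(k.expression_multipliers or {})
        sigma = mult.pop("__global_sigma__", None)
        if sigma is not None:
            draw = rng.lognormal(-0.5 * sigma**2, sigma, size=len(models))
            for m, d in zip(models, draw):
                mult.setdefault(m.gene_id, 1.0)
                mult[m.gene_id] = mult[m.gene_id] * float(d)
            k = replace(k, expression_multipliers=mult)
        out.append(k)
    return out


def simulate_scenario(scenario: str = "study_design", seed: int = 0,
                      include_fibroblast: bool = True, **config_overrides):
    """Generate a named cohort scenario.

    Scenarios
    ---------
    ``study_design``
        The full cohort described above (Table-style: +2, +1, 0, 0 extra
        autosomes plus the biactive-X reference line and the fibroblast).
    ``all_disomic``
        Same line roster with every autosome disomic (specificity null).
    ``two_trisomy``
        One male line trisomic for autosomes 19 and 20, four euploid lines.
    ``single_trisomy``
        One Xi-female line trisomic for autosome 20, four euploid lines.

    Returns ``(counts, annotation, truth, config)``.
    """
    config = default_config(seed=seed, **config_overrides)
    rng = np.random.default_rng(config.seed)
    models = build_gene_model(config, rng=rng)
    models, panels = assign_marker_genes(models)
    annotation = annotation_from_models(models, marker_panels=panels)

    if scenario == "study_design":
        specs = study_design_karyotypes(include_fibroblast=include_fibroblast)
    elif scenario == "all_disomic":
        specs = study_design_karyotypes(include_fibroblast=include_fibroblast)
        specs = [replace(k, copy_number={}) for k in specs]
    elif scenario == "two_trisomy":
        specs = study_design_karyotypes(include_fibroblast=False)
        specs = [replace(k, copy_number={"19": 3, "20": 3} if k.sample_id == "ESC1" else {})
                 for k in specs]
    elif scenario == "single_trisomy":
        specs = study_design_karyotypes(include_fibroblast=False)
        specs = [replace(k, copy_number={"20": 3} if k.sample_id == "ESC2" else {})
                 for k in specs]
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    specs = _expand_global_multipliers(specs, models, rng)
    counts, truth = simulate_counts(models, specs, config, rng=rng)
    return counts, annotation, truth, config


SCENARIOS = ("study_design", "all_disomic", "two_trisomy", "single_trisomy")
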
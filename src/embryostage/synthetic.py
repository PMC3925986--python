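"""Seeded stage-series count simulator with planted ground truth.

The generator emulates the study design end to end: pooled-embryo libraries
along an ordered stage series (oocyte .. morula plus the two blastocyst
halves) for up to three conditions (e.g. mouse in-vivo, pig in-vivo, pig
SCNT), each with its own zygotic-genome-activation (ZGA) stage.

Gene classes
------------
``maternal``   decaying maternal deposit: high in the oocyte, exponential
               decay from the ZGA stage onward.
``stable``     stable maternal deposit (constitutive transcripts): flat across
               the whole series.  Together with ``maternal`` it forms the
               maternal-deposit truth set (any oocyte-expressed transcript is
               a maternal deposit by the oocyte-RPKM rule).
``zygotic``    near-silent before ZGA, induced ``zygotic_fold``-fold at the
               ZGA stage and kept on afterwards.
``icm`` / ``te``  lineage programs expressed in the latent ICM / TE
               blastocyst profiles (``icm_fold`` above the opposite lineage);
               half of each program switches on already in the morula.
``noise``      low-expressed background, below every threshold.

The physically split blastocyst is modelled literally: the ICMTE half's
expected expression is ``f * ICM + (1 - f) * TE`` of the latent lineage
profiles, the TE half is pure TE.

Absolute scale
--------------
RPKM is compositional, so absolute levels cannot be planted directly; the
generator budgets total expression mass (sum of RPKM x length = 1e9 at the
oocyte stage) and lets the ``stable`` class absorb the budget remainder.
Exact expected RPKM per gene, stage and condition is stored in the truth
table.

Noise
-----
Overdispersion enters as a per-gene multiplicative Gamma(1/d, d) effect
shared across all samples of a condition, plus per-sample Poisson sampling;
marginally each count is negative-binomial with dispersion ``d`` around its
length- and library-scaled mean, while between-sample count ratios remain
conditionally binomial — the regime a replicate-free pooled-library test
assumes.  Dispersion 0 yields deterministic rounded expected counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CLEAVAGE_STAGES,
    DEFAULT_STAGE_ORDER,
    CountMatrix,
    ExpressionMatrix,
    GeneAnnotation,
    OrthologTable,
    SampleSheet,
    ValidationError,
)

log = logging.getLogger("embryostage")

TOTAL_MASS = 1e9  # sum of RPKM * length budget at the oocyte stage
CLASSES = ("maternal", "stable", "zygotic", "icm", "te", "noise")


@dataclass(frozen=True)
class ConditionSpec:
    """One stage series: a species/condition with its own ZGA stage.

    ``maternal_share`` / ``zygotic_share`` give the fraction of the reference
    condition's maternal-deposit / zygotic program this condition retains
    (demoted deposit genes become zygotic-only here; demoted zygotic genes
    stay flat).  ``dysregulated_fraction`` applies a flat random fold change
    to that fraction of genes (global dysregulation without stage dynamics).
    """

    name: str
    species: str
    zga_stage: str = "4cell"
    maternal_share: float = 1.0
    zygotic_share: float = 1.0
    dysregulated_fraction: float = 0.0


#: Default study layout: ZGA at the 2-cell stage in mouse, the 4-cell stage in
#: normal pig embryos and the 8-cell stage in pig SCNT embryos; sharing
#: defaults mirror the reported overlap levels (81.3% / 50.0% with SCNT,
#: 47.3% / 17.7% with mouse).
DEFAULT_CONDITIONS: tuple[ConditionSpec, ...] = (
    ConditionSpec("pig_invivo", "pig", "4cell"),
    ConditionSpec("pig_scnt", "pig", "8cell", 0.813, 0.50, 0.05),
    ConditionSpec("mouse_invivo", "mouse", "2cell", 0.473, 0.177, 0.0),
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_genes: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGE_ORDER
    conditions: tuple[ConditionSpec, ...] = DEFAULT_CONDITIONS
    frac_maternal: float = 0.20
    frac_stable: float = 0.35
    frac_zygotic: float = 0.15
    frac_icm: float = 0.03
    frac_te: float = 0.03
    maternal_decay: float = 0.15  # retained fraction per stage after ZGA
    zygotic_fold: float = 8.0
    icm_fold: float = 8.0
    mixing_fraction: float = 0.5  # ICM share f of the ICMTE half
    dispersion: float = 0.1
    library_size: float = 3e6
    library_sigma: float = 0.2
    length_log_mean: float = float(np.log(1500.0))
    length_log_sigma: float = 0.5
    replicates: int = 2
    ortholog_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_maternal,
            self.frac_stable,
            self.frac_zygotic,
            self.frac_icm,
            self.frac_te,
            self.mixing_fraction,
            self.ortholog_fraction,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise ValidationError("all fractions must lie in [0, 1]")
        if sum(fracs[:5]) > 1.0 + 1e-9:
            raise ValidationError("class fractions must sum to at most 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        for cond in self.conditions:
            if cond.zga_stage not in self.stages:
                raise ValidationError(
                    f"ZGA stage {cond.zga_stage!r} of {cond.name!r} not in stage list"
                )
        species = {c.species for c in self.conditions}
        if len(species) > 2:
            raise ValidationError("at most two species are supported")


@dataclass(frozen=True)
class TruthTable:
    """Planted ground truth for every condition.

    ``classes`` holds the per-condition class label and morula-coexpression
    flag per gene; ``expected_rpkm`` the exact expected RPKM per gene and
    stage; the rule-based ``maternal`` / ``zygotic`` sets apply the
    classification rules to the expected values (so they are exactly what a
    noiseless run recovers); ``icm_specific`` / ``te_specific`` are the
    planted lineage programs.
    """

    classes: dict[str, pd.DataFrame]
    expected_rpkm: dict[str, pd.DataFrame]
    maternal: dict[str, frozenset[str]]
    zygotic: dict[str, frozenset[str]]
    icm_specific: dict[str, frozenset[str]]
    te_specific: dict[str, frozenset[str]]
    zga_stage: dict[str, str]


@dataclass(frozen=True)
class SimulatedStudy:
    config: GeneratorConfig
    counts: dict[str, CountMatrix]  # per condition
    annotations: dict[str, GeneAnnotation]  # per species
    orthologs: OrthologTable | None
    truth: TruthTable


def _class_assignment(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = cfg.n_genes
    counts = {
        "maternal": int(round(cfg.frac_maternal * n)),
        "stable": int(round(cfg.frac_stable * n)),
        "zygotic": int(round(cfg.frac_zygotic * n)),
        "icm": int(round(cfg.frac_icm * n)),
        "te": int(round(cfg.frac_te * n)),
    }
    labels = np.array(
        sum(([c] * k for c, k in counts.items()), [])
        + ["noise"] * (n - sum(counts.values())),
        dtype=object,
    )
    rng.shuffle(labels)
    return labels


def _base_levels(
    labels: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-gene archetype level parameters in (uncalibrated) RPKM-like units."""
    n = labels.size
    base = np.zeros(n)
    m = labels == "maternal"
    base[m] = np.clip(rng.lognormal(np.log(30.0), 0.6, m.sum()), 8.0, None)
    s = labels == "stable"
    base[s] = rng.lognormal(np.log(30.0), 1.0, s.sum())  # rescaled by mass budget
    z = labels == "zygotic"
    base[z] = np.clip(rng.lognormal(np.log(1.2), 0.3, z.sum()), 0.8, 2.4)
    lineage = (labels == "icm") | (labels == "te")
    base[lineage] = np.clip(rng.lognormal(np.log(3.5), 0.25, lineage.sum()), 2.5, 6.0)
    nz = labels == "noise"
    base[nz] = np.minimum(rng.lognormal(np.log(0.3), 0.7, nz.sum()), 2.4)
    early = np.clip(rng.lognormal(np.log(1.2), 0.3, n), 0.5, 2.4)  # lineage pre-level
    coexpressed = rng.random(n) < 0.5  # lineage genes already on in the morula
    return {"base": base, "early": early, "coexpressed": coexpressed}


def _condition_classes(
    template: np.ndarray,
    cond: ConditionSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Derive a condition's class labels from the template via share rules.

    Returns (labels, promoted_mask); promoted noise genes become maternal
    here and need fresh level draws.
    """
    labels = template.copy()
    deposit = np.flatnonzero((template == "maternal") | (template == "stable"))
    n_demote = int(round((1.0 - cond.maternal_share) * deposit.size))
    demoted = rng.choice(deposit, size=n_demote, replace=False) if n_demote else np.array([], int)
    labels[demoted] = "zygotic_late"  # deposit gene of the reference, zygotic-only here

    zyg = np.flatnonzero(template == "zygotic")
    n_zdemote = int(round((1.0 - cond.zygotic_share) * zyg.size))
    zdemoted = rng.choice(zyg, size=n_zdemote, replace=False) if n_zdemote else np.array([], int)
    labels[zdemoted] = "silent"  # never induced in this condition

    noise = np.flatnonzero(template == "noise")
    n_promote = min(n_demote, noise.size // 2)
    promoted = rng.choice(noise, size=n_promote, replace=False) if n_promote else np.array([], int)
    labels[promoted] = "maternal"
    promoted_mask = np.zeros(template.size, dtype=bool)
    promoted_mask[promoted] = True
    return labels, promoted_mask


def _expected_profiles(
    labels: np.ndarray,
    levels: dict[str, np.ndarray],
    cfg: GeneratorConfig,
    cond: ConditionSpec,
) -> pd.DataFrame:
    """Archetype expression per gene and stage (before gene effects)."""
    n = labels.size
    base, early, coexp = levels["base"], levels["early"], levels["coexpressed"]
    cleavage = [s for s in cfg.stages if s in CLEAVAGE_STAGES]
    zga_i = cleavage.index(cond.zga_stage)
    x = pd.DataFrame(0.0, index=np.arange(n), columns=list(cfg.stages))

    lat_icm = np.zeros(n)
    lat_te = np.zeros(n)
    for i, st in enumerate(cleavage):
        col = np.zeros(n)
        post = i >= zga_i
        decay = cfg.maternal_decay ** max(0, i - zga_i + 1)
        col[labels == "maternal"] = base[labels == "maternal"] * decay
        col[labels == "stable"] = base[labels == "stable"]
        z = labels == "zygotic"
        col[z] = base[z] * (cfg.zygotic_fold if post else 1.0)
        zl = labels == "zygotic_late"
        col[zl] = base[zl] if post else 0.5
        sil = labels == "silent"
        col[sil] = base[sil]  # stays at the silent pre-level throughout
        for lab in ("icm", "te"):
            sel = labels == lab
            col[sel] = early[sel]
            if st == "morula":
                on = sel & coexp
                col[on] = base[on] * cfg.icm_fold
        nz = labels == "noise"
        col[nz] = base[nz]
        x[st] = col

    # latent blastocyst lineage profiles
    blast_decay = cfg.maternal_decay ** max(0, len(cleavage) - zga_i + 1)
    for lab, sel in (
        ("maternal", labels == "maternal"),
        ("stable", labels == "stable"),
        ("noise", labels == "noise"),
        ("silent", labels == "silent"),
    ):
        lat = base[sel] * (blast_decay if lab == "maternal" else 1.0)
        lat_icm[sel] = lat
        lat_te[sel] = lat
    for lab in ("zygotic", "zygotic_late"):
        sel = labels == lab
        lat_icm[sel] = base[sel] * (cfg.zygotic_fold if lab == "zygotic" else 1.0)
        lat_te[sel] = lat_icm[sel]
    icm_sel = labels == "icm"
    lat_icm[icm_sel] = base[icm_sel] * cfg.icm_fold
    lat_te[icm_sel] = base[icm_sel]
    te_sel = labels == "te"
    lat_icm[te_sel] = base[te_sel]
    lat_te[te_sel] = base[te_sel] * cfg.icm_fold

    f = cfg.mixing_fraction
    if "ICMTE" in cfg.stages:
        x["ICMTE"] = f * lat_icm + (1.0 - f) * lat_te
    if "TE" in cfg.stages:
        x["TE"] = lat_te
    return x


def generate(cfg: GeneratorConfig) -> SimulatedStudy:
    """Simulate count tables, annotation, orthologs and the truth table."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    template = _class_assignment(cfg, rng)
    levels = _base_levels(template, cfg, rng)
    lengths = np.round(
        rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma, n)
    ).clip(600, None).astype(np.int64)

    # mass-budget calibration of the stable class at the reference oocyte stage
    ref = cfg.conditions[0]
    x_ref = _expected_profiles(template, levels, cfg, ref)
    stable = template == "stable"
    nonstable_mass = float((x_ref.loc[~stable, "oocyte"] * lengths[~stable]).sum())
    stable_mass = float((x_ref.loc[stable, "oocyte"] * lengths[stable]).sum())
    if nonstable_mass >= TOTAL_MASS:
        raise ValidationError("expression mass budget exceeded; reduce levels or n_genes")
    gamma = (TOTAL_MASS - nonstable_mass) / stable_mass
    levels["base"] = levels["base"].copy()
    levels["base"][stable] = np.clip(levels["base"][stable] * gamma, 5.0, None)

    species_names = {c.species for c in cfg.conditions}
    gene_ids = {
        sp: [f"{sp}_g{i:05d}" for i in range(n)] for sp in sorted(species_names)
    }
    annotations = {
        sp: GeneAnnotation(pd.Series(lengths, index=gene_ids[sp]))
        for sp in sorted(species_names)
    }

    orthologs = None
    if len(species_names) == 2:
        sp_a, sp_b = sorted(species_names)
        paired = np.sort(
            rng.choice(n, size=int(round(cfg.ortholog_fraction * n)), replace=False)
        )
        orthologs = OrthologTable(
            pd.DataFrame(
                {
                    "gene_a": [gene_ids[sp_a][i] for i in paired],
                    "gene_b": [gene_ids[sp_b][i] for i in paired],
                }
            )
        )

    counts: dict[str, CountMatrix] = {}
    classes: dict[str, pd.DataFrame] = {}
    expected: dict[str, pd.DataFrame] = {}
    maternal_truth: dict[str, frozenset[str]] = {}
    zygotic_truth: dict[str, frozenset[str]] = {}
    icm_truth: dict[str, frozenset[str]] = {}
    te_truth: dict[str, frozenset[str]] = {}
    zga_truth: dict[str, str] = {}

    for cond in cfg.conditions:
        crng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        labels, promoted = _condition_classes(template, cond, crng)
        lv = dict(levels)
        lv["base"] = levels["base"].copy()
        if promoted.any():  # fresh maternal-deposit levels for promoted genes
            lv["base"][promoted] = np.clip(
                crng.lognormal(np.log(30.0), 0.6, int(promoted.sum())), 8.0, None
            )
        x = _expected_profiles(labels, lv, cfg, cond)

        if cond.dysregulated_fraction > 0:
            dys = crng.random(n) < cond.dysregulated_fraction
            x.loc[dys] = x.loc[dys].mul(
                crng.lognormal(0.0, 0.5, int(dys.sum())), axis=0
            )

        if cfg.dispersion > 0:  # shared per-gene expression effect
            lam = crng.gamma(1.0 / cfg.dispersion, cfg.dispersion, n)
            x = x.mul(lam, axis=0)

        ids = gene_ids[cond.species]
        x.index = ids

        # truth from exact expected RPKM
        mass = (x.mul(lengths, axis=0)).sum(axis=0)  # per stage
        exp_rpkm = x * (TOTAL_MASS / mass)
        expected[cond.name] = exp_rpkm
        classes[cond.name] = pd.DataFrame(
            {"gene_class": labels, "morula_coexpressed": levels["coexpressed"]},
            index=ids,
        )
        oo = exp_rpkm["oocyte"]
        maternal_truth[cond.name] = frozenset(oo.index[oo > 3.0])
        cleavage = [s for s in cfg.stages if s in CLEAVAGE_STAGES]
        zga_i = cleavage.index(cond.zga_stage)
        zyg: set[str] = set()
        for a, b in zip(cleavage[:-1], cleavage[1:]):
            fold = exp_rpkm[b] / exp_rpkm[a].clip(lower=1e-12)
            zyg |= set(exp_rpkm.index[(fold > 2.0) & (exp_rpkm[b] > 3.0)])
            if b == cond.zga_stage:
                break
        zygotic_truth[cond.name] = frozenset(zyg & set(oo.index[oo <= 3.0]))
        icm_truth[cond.name] = frozenset(np.array(ids)[labels == "icm"])
        te_truth[cond.name] = frozenset(np.array(ids)[labels == "te"])
        zga_truth[cond.name] = cond.zga_stage

        # draw counts
        sample_rows = []
        cols = {}
        for stage in cfg.stages:
            for rep in range(1, cfg.replicates + 1):
                sid = f"{cond.name}_{stage}_r{rep}"
                lib = crng.lognormal(np.log(cfg.library_size), cfg.library_sigma)
                mu = lib * x[stage].to_numpy() * lengths / TOTAL_MASS
                if cfg.dispersion > 0:
                    col = crng.poisson(mu)
                else:
                    col = np.round(mu).astype(np.int64)
                cols[sid] = col
                sample_rows.append((sid, stage, cond.name, cond.species, rep))
        sheet = SampleSheet(
            pd.DataFrame(
                sample_rows,
                columns=["sample_id", "stage", "condition", "species", "replicate"],
            ),
            stage_order=cfg.stages,
        )
        counts[cond.name] = CountMatrix(pd.DataFrame(cols, index=ids), sheet)

    truth = TruthTable(
        classes=classes,
        expected_rpkm=expected,
        maternal=maternal_truth,
        zygotic=zygotic_truth,
        icm_specific=icm_truth,
        te_specific=te_truth,
        zga_stage=zga_truth,
    )
    return SimulatedStudy(cfg, counts, annotations, orthologs, truth)


def truth_eval(
    called: set[str] | frozenset[str],
    true: set[str] | frozenset[str],
    universe: set[str] | frozenset[str],
) -> dict[str, float]:
    """Confusion-matrix metrics for a called gene set against planted truth."""
    called, true, universe = set(called), set(true), set(universe)
    tp = len(called & true)
    fp = len(called - true)
    fn = len(true - called)
    tn = len(universe - called - true)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    union = len(called | true)
    jac = tp / union if union else 1.0
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    f1 = (
        2 * prec * sens / (prec + sens)
        if (tp + fp) and (tp + fn) and (prec + sens) > 0
        else 0.0
    )
    return {
        "sensitivity": sens,
        "specificity": spec,
        "fdr": fdr,
        "jaccard": jac,
        "f1": f1,
        "tp": float(tp),
        "fp": float(fp),
        "fn": float(fn),
        "tn": float(tn),
    }


def simulate_two_group(
    n_genes: int = 5000,
    n_de: int = 200,
    fold: float = 8.0,
    depth: float = 1e6,
    dispersion: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, float]:
    """Two pooled libraries with planted fold changes.

    Gene-level overdispersion is a shared Gamma effect (see module docstring);
    the first `n_de` genes are `fold`-fold up in library A.  Returns
    (k1, k2, is_de, n1, n2).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = rng.lognormal(0.0, 1.0, n_genes)
    lam = (
        rng.gamma(1.0 / dispersion, dispersion, n_genes) if dispersion > 0 else 1.0
    )
    expr = base * lam
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[:n_de] = True
    expr_a = expr * np.where(is_de, fold, 1.0)
    mu_a = expr_a / expr_a.sum() * depth
    mu_b = expr / expr.sum() * depth
    k1 = rng.poisson(mu_a)
    k2 = rng.poisson(mu_b)
    return k1, k2, is_de, float(k1.sum()), float(k2.sum())


def simulate_marker_network(
    markers: Sequence[str],
    n_targets: int = 20,
    n_noise: int = 200,
    n_stages: int = 8,
    target_r: float = 0.98,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Planted marker-module profiles for network-recovery tests.

    Each marker gets `n_targets` noisy affine copies of its stage profile
    (noise sized so the true |Pearson r| is about `target_r`); `n_noise`
    unrelated genes get independent profiles.  Returns (stage-mean log10
    expression profile table genes x stages, set of true (marker, target)
    edges).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages = [f"s{i}" for i in range(n_stages)]
    rows = {}
    truth: set[tuple[str, str]] = set()
    noise_scale = float(np.sqrt(1.0 / target_r**2 - 1.0))
    # log10-RPKM profiles kept well inside (0, 3) so nothing clips at zero
    # expression and every gene clears the RPKM > 3 floor at some stage.
    # Marker profiles are redrawn until pairwise |r| <= 0.8 so the planted
    # modules are distinguishable at the 0.9 edge threshold.
    accepted: list[np.ndarray] = []
    for m in markers:
        for _ in range(1000):
            prof = rng.normal(1.5, 0.3, n_stages)
            if all(abs(np.corrcoef(prof, q)[0, 1]) <= 0.8 for q in accepted):
                break
        else:  # pragma: no cover - astronomically unlikely for sane sizes
            raise ValidationError("could not draw sufficiently distinct marker profiles")
        accepted.append(prof)
        rows[m] = prof
        sd = prof.std()
        for t in range(n_targets):
            gene = f"{m}_target{t:02d}"
            a = rng.uniform(0.5, 1.2) * rng.choice([-1.0, 1.0])
            c = rng.uniform(1.3, 1.7)
            noisy = (
                c
                + a * (prof - prof.mean())
                + rng.normal(0.0, abs(a) * sd * noise_scale, n_stages)
            )
            rows[gene] = noisy
            truth.add((m, gene))
    for j in range(n_noise):
        rows[f"noise{j:04d}"] = rng.normal(1.5, 0.3, n_stages)
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=stages)
    return profiles, truth


def profiles_to_expression(
    profiles: pd.DataFrame, condition: str = "sim", species: str = "sim"
) -> ExpressionMatrix:
    """Wrap log10 stage profiles as an RPKM expression matrix (one sample per
    stage), inverting the log10(x + 1) transform so downstream log transforms
    recover the profiles exactly."""
    stages = tuple(profiles.columns)
    rpkm_vals = np.clip(10.0 ** profiles.to_numpy(dtype=float) - 1.0, 0.0, None)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": list(stages),
                "stage": list(stages),
                "condition": condition,
                "species": species,
                "replicate": 1,
            }
        ),
        stage_order=stages,
    )
    values = pd.DataFrame(rpkm_vals, index=profiles.index, columns=list(stages))
    return ExpressionMatrix(values, sheet)
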
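"""Synthetic-data generators for every pipeline stage.

Each generator is deterministic given its seed and returns the simulated
input *plus a truth record*, so downstream stages can be scored in closed
loop without any external data.  Defaults encode the study conditions the
pipeline is meant to analyse:

* case-control cohort — 190 cases at carrier frequency 0.105 vs 1,063
  controls at 0.029 (a ~10.5% vs ~2.9% carrier split);
* family — two affected siblings, an affected distant relative (a paternal
  great aunt) and an unaffected mother, with one planted dominant variant
  shared by all affecteds and absent from the mother, on a background of
  independent population variants transmitted Mendelianly;
* survival — 10 mutant-carrier vs 62 wild-type subjects with exponential
  event times (hazard ratio 3 by default) and uniform censoring;
* expression — 8 matched tissue pairs (5 atrial septum, 3 right ventricle)
  with MYH7 planted at 3.46-fold upregulation in mutant members;
* densitometry — 4 pairs x 5 replicates with a +62% genotype effect on the
  band/GAPDH ratio.

Carrier simulation is subject-level (carrier yes/no), matching the
carrier-collapsing association test; allele-level simulation is out of
scope.  Expression noise is log-normal with per-pair intercepts — the
weakest structure under which the downstream paired test is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import (
    CohortGenotypes,
    Pedigree,
    PedigreeMember,
    read_variant_table,
    table1_fixture_path,
    variant_id,
)
from .expression import MatchedPairSet

__all__ = [
    "CohortConfig",
    "PedigreeConfig",
    "SurvivalConfig",
    "ExpressionConfig",
    "DensitometryConfig",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_multigene_cohort",
    "PedigreeSimulation",
    "simulate_pedigree_vcf",
    "simulate_survival",
    "simulate_expression",
    "simulate_densitometry",
]


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int = 190
    n_controls: int = 1063
    f_case: float = 0.105
    f_ctrl: float = 0.029

    def __post_init__(self) -> None:
        if not (0 <= self.f_case <= 1 and 0 <= self.f_ctrl <= 1):
            raise InputError("carrier frequencies must lie in [0, 1]")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InputError("cohort sizes must be positive")


@dataclass(frozen=True)
class PedigreeConfig:
    n_background_variants: int = 500
    background_freq: float = 0.01  # population alt-allele frequency


@dataclass(frozen=True)
class SurvivalConfig:
    n_mut: int = 10
    n_wt: int = 62
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.05  # events per year in the wild-type group
    censoring_fraction: float = 0.2


@dataclass(frozen=True)
class ExpressionConfig:
    n_pairs: int = 8  # 5 atrial septum + 3 right ventricle
    n_genes: int = 2000
    planted_folds: tuple[tuple[str, float], ...] = (("MYH7", 3.46),)
    residual_sd_log2: float = 0.2  # per-sample noise, log2 scale (~15% CV)
    pair_sd_log2: float = 1.0  # between-pair intercept spread


@dataclass(frozen=True)
class DensitometryConfig:
    n_pairs: int = 4
    n_replicates: int = 5
    effect: float = 0.62  # fractional increase of MUT over WT
    noise_sd: float = 0.3  # natural-log scale
    pair_sd: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of per-stage configs plus the master seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pedigree: PedigreeConfig = field(default_factory=PedigreeConfig)
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    densitometry: DensitometryConfig = field(default_factory=DensitometryConfig)


def _variant_templates() -> pd.DataFrame:
    """Distinct variants from the packaged table, used as qualifying-variant
    templates (a realistic mix of head/neck/tail, novel/known, missense/LoF)."""
    records = read_variant_table(table1_fixture_path())
    seen: dict[str, dict] = {}
    for r in records:
        seen.setdefault(
            r.variant_name,
            {
                "id": variant_id("14", r.coordinate, r.ref, r.alt),
                "chrom": "14",
                "pos": r.coordinate,
                "ref": r.ref,
                "alt": r.alt,
                "gene": "MYH6",
                "variant_name": r.variant_name,
            },
        )
    return pd.DataFrame(list(seen.values())).set_index("id")


def simulate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> tuple[CohortGenotypes, dict]:
    """Case-control carrier cohort: each subject independently a carrier.

    Carriers receive one heterozygous qualifying variant drawn uniformly from
    the template set.  Truth records the realised carrier counts and ids.
    """
    rng = np.random.default_rng(seed)
    templates = _variant_templates()
    subjects = [f"case_{i:04d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:04d}" for i in range(config.n_controls)
    ]
    labels = pd.Series(
        ["case"] * config.n_cases + ["control"] * config.n_controls,
        index=subjects,
        name="label",
    )
    freqs = np.concatenate(
        [
            np.full(config.n_cases, config.f_case),
            np.full(config.n_controls, config.f_ctrl),
        ]
    )
    is_carrier = rng.random(len(subjects)) < freqs
    counts = pd.DataFrame(
        0.0, index=pd.Index(subjects, name="subject"), columns=templates.index
    )
    choice = rng.integers(0, len(templates), size=len(subjects))
    for i, subject in enumerate(subjects):
        if is_carrier[i]:
            counts.iloc[i, choice[i]] = 1.0
    cohort = CohortGenotypes(allele_counts=counts, variants=templates, labels=labels)
    truth = {
        "case_carriers": int(is_carrier[: config.n_cases].sum()),
        "control_carriers": int(is_carrier[config.n_cases :].sum()),
        "carrier_subjects": [s for s, c in zip(subjects, is_carrier) if c],
    }
    return cohort, truth


def simulate_multigene_cohort(
    n_genes: int = 20,
    planted_gene: str | None = "GENE01",
    config: CohortConfig = CohortConfig(),
    null_freq: float | None = None,
    seed: int = 0,
) -> tuple[CohortGenotypes, dict]:
    """Cohort with one carrier-status variant per gene, for burden scans.

    The planted gene (if any) uses the case/control frequencies of
    ``config``; every other gene is null at ``null_freq`` (defaults to the
    control frequency) in cases and controls alike.
    """
    rng = np.random.default_rng(seed)
    if null_freq is None:
        null_freq = config.f_ctrl
    genes = [f"GENE{i + 1:02d}" for i in range(n_genes)]
    if planted_gene is not None and planted_gene not in genes:
        raise InputError(f"planted gene {planted_gene!r} not among {n_genes} genes")
    subjects = [f"case_{i:04d}" for i in range(config.n_cases)] + [
        f"ctrl_{i:04d}" for i in range(config.n_controls)
    ]
    labels = pd.Series(
        ["case"] * config.n_cases + ["control"] * config.n_controls,
        index=subjects,
        name="label",
    )
    n_total = len(subjects)
    data = {}
    meta_rows = []
    for g_idx, gene in enumerate(genes):
        if gene == planted_gene:
            freqs = np.concatenate(
                [
                    np.full(config.n_cases, config.f_case),
                    np.full(config.n_controls, config.f_ctrl),
                ]
            )
        else:
            freqs = np.full(n_total, null_freq)
        vid = variant_id(str(g_idx + 1), 1000 + g_idx, "A", "G")
        data[vid] = (rng.random(n_total) < freqs).astype(float)
        meta_rows.append(
            {"id": vid, "chrom": str(g_idx + 1), "pos": 1000 + g_idx, "ref": "A",
             "alt": "G", "gene": gene}
        )
    cohort = CohortGenotypes(
        allele_counts=pd.DataFrame(data, index=pd.Index(subjects, name="subject")),
        variants=pd.DataFrame(meta_rows).set_index("id"),
        labels=labels,
    )
    return cohort, {"planted_gene": planted_gene, "genes": genes}


# ---------------------------------------------------------------------------
# family simulation
# ---------------------------------------------------------------------------

#: genotyped members of the study family template: great aunt II:4, father
#: III:1, mother III:2, affected children IV:1 and IV:3
_FAMILY_MEMBERS = [
    PedigreeMember(id="II:4", father_id=None, mother_id=None, sex="female", affected=True),
    PedigreeMember(id="III:1", father_id=None, mother_id=None, sex="male", affected=True),
    PedigreeMember(id="III:2", father_id=None, mother_id=None, sex="female", affected=False),
    PedigreeMember(id="IV:1", father_id="III:1", mother_id="III:2", sex="male", affected=True),
    PedigreeMember(id="IV:3", father_id="III:1", mother_id="III:2", sex="female", affected=True),
]

PLANTED_VARIANT_ID = variant_id("14", 23869999, "C", "G")


@dataclass
class PedigreeSimulation:
    genotypes: CohortGenotypes
    pedigree: Pedigree
    gene_map: pd.DataFrame  # gene, chrom, start, end (1-based closed)
    heart_expression: pd.Series  # gene -> TPM
    truth: dict


def expected_background_leakage(freq: float, n_variants: int) -> float:
    """Analytic expectation of background variants passing the family filter.

    A background variant passes iff the independent great aunt carries it
    (1 - (1-f)^2), the mother is homozygous reference ((1-f)^2), and both
    children inherit an alt allele from the father (f(1-f)/2 + f^2 under
    Mendelian transmission given a reference mother).
    """
    p_aunt = 1 - (1 - freq) ** 2
    p_mother_ref = (1 - freq) ** 2
    p_both_children = freq * (1 - freq) / 2 + freq**2
    return n_variants * p_aunt * p_mother_ref * p_both_children


def simulate_pedigree_vcf(
    config: PedigreeConfig = PedigreeConfig(), seed: int = 0
) -> PedigreeSimulation:
    """Family genotypes with one planted dominant variant plus background.

    The planted variant is heterozygous in every affected member (II:4,
    III:1, IV:1, IV:3) and absent in the unaffected mother (III:2).
    Background variants draw founder genotypes binomially at the population
    frequency and transmit Mendelianly to the children; they are scattered
    over 19 synthetic background genes so the gene-level reduction mirrors a
    multi-candidate outcome.
    """
    rng = np.random.default_rng(seed)
    members = [m.id for m in _FAMILY_MEMBERS]
    n_bg = config.n_background_variants
    f = config.background_freq

    # founders: II:4 (independent), III:1, III:2; children transmit from parents
    founders = {m: rng.binomial(2, f, size=n_bg).astype(float) for m in
                ("II:4", "III:1", "III:2")}

    def _gamete(parent_gt: np.ndarray) -> np.ndarray:
        # transmit one allele: het -> Bernoulli(1/2); hom alt -> 1; hom ref -> 0
        return np.where(
            parent_gt == 1, rng.integers(0, 2, size=parent_gt.shape), parent_gt / 2
        ).astype(float)

    children = {
        child: _gamete(founders["III:1"]) + _gamete(founders["III:2"])
        for child in ("IV:1", "IV:3")
    }

    n_bg_genes = 19
    gene_names = [f"BG{i + 1:02d}" for i in range(n_bg_genes)]
    gene_span = 10_000
    positions = np.sort(rng.choice(np.arange(1, gene_span * n_bg_genes), size=n_bg,
                                   replace=False))
    # gene assignment follows position so each variant falls inside its interval
    bg_gene_idx = (positions - 1) // gene_span

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for j in range(n_bg):
        vid = variant_id("1", int(positions[j]), "A", "T")
        columns[vid] = np.array(
            [founders["II:4"][j], founders["III:1"][j], founders["III:2"][j],
             children["IV:1"][j], children["IV:3"][j]]
        )
        meta_rows.append(
            {"id": vid, "chrom": "1", "pos": int(positions[j]), "ref": "A",
             "alt": "T", "gene": gene_names[bg_gene_idx[j]]}
        )
    # planted dominant variant in the MYH6 interval
    columns[PLANTED_VARIANT_ID] = np.array([1.0, 1.0, 0.0, 1.0, 1.0])
    meta_rows.append(
        {"id": PLANTED_VARIANT_ID, "chrom": "14", "pos": 23869999, "ref": "C",
         "alt": "G", "gene": "MYH6"}
    )
    genotypes = CohortGenotypes(
        allele_counts=pd.DataFrame(columns, index=pd.Index(members, name="subject")),
        variants=pd.DataFrame(meta_rows).set_index("id"),
    )
    gene_map = pd.DataFrame(
        [
            {
                "gene": gene_names[i],
                "chrom": "1",
                "start": i * gene_span + 1,
                "end": (i + 1) * gene_span,
            }
            for i in range(n_bg_genes)
        ]
        + [{"gene": "MYH6", "chrom": "14", "start": 23851199, "end": 23877485}]
    )
    heart_expression = pd.Series(
        np.round(rng.uniform(0.0, 5.0, size=n_bg_genes), 3), index=gene_names
    )
    heart_expression["MYH6"] = 5000.0  # highly expressed in heart
    pedigree = Pedigree(family_id="F_MYH6_R443P", members=list(_FAMILY_MEMBERS))
    truth = {
        "planted_variant": PLANTED_VARIANT_ID,
        "planted_gene": "MYH6",
        "expected_background_leakage": expected_background_leakage(f, n_bg),
    }
    return PedigreeSimulation(
        genotypes=genotypes,
        pedigree=pedigree,
        gene_map=gene_map,
        heart_expression=heart_expression,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# survival / expression / densitometry
# ---------------------------------------------------------------------------


def simulate_survival(
    config: SurvivalConfig = SurvivalConfig(), seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Two-group survival table with exponential event times.

    Wild-type hazard is ``baseline_hazard``; mutant-carrier hazard is
    ``hazard_ratio`` times that.  A ``censoring_fraction`` of subjects is
    censored at a uniform time before their latent event.  Ages are emitted
    (>= 6 years) so the study's age-eligibility filter is a no-op on
    defaults.
    """
    rng = np.random.default_rng(seed)
    n = config.n_mut + config.n_wt
    groups = np.array(["MUT"] * config.n_mut + ["WT"] * config.n_wt)
    hazards = np.where(
        groups == "MUT",
        config.baseline_hazard * config.hazard_ratio,
        config.baseline_hazard,
    )
    latent = rng.exponential(1.0 / hazards)
    censored = rng.random(n) < config.censoring_fraction
    times = np.where(censored, rng.uniform(0, latent), latent)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "group": groups,
            "time_years": np.round(times, 4),
            "event": (~censored).astype(int),
            "age_years": np.round(6.0 + rng.uniform(0, 12, size=n), 1),
        }
    )
    truth = {
        "hazard_ratio": config.hazard_ratio,
        "n_mut": config.n_mut,
        "n_wt": config.n_wt,
        "n_censored": int(censored.sum()),
    }
    return df, truth


def simulate_expression(
    config: ExpressionConfig = ExpressionConfig(), seed: int = 0
) -> tuple[MatchedPairSet, dict]:
    """Matched-pair TPM matrix with planted fold changes in mutant samples.

    Per gene: a baseline log2 level ~ U(3, 10), a per-pair intercept
    (SD ``pair_sd_log2``, shared by both members of a pair, hence absorbed
    by pairing) and per-sample residual noise (SD ``residual_sd_log2``).
    Genes in ``planted_folds`` gain log2(fold) in the mutant member only.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_pairs = config.n_genes, config.n_pairs
    genes = [f"G{i:04d}" for i in range(n_genes)]
    planted = dict(config.planted_folds)
    # make sure the named genes (and the burden gene, reported separately)
    # exist in the matrix
    specials = list(dict.fromkeys([*planted, "MYH6"]))
    for i, name in enumerate(specials):
        genes[i] = name
    baseline = rng.uniform(3.0, 10.0, size=n_genes)
    pair_effect = rng.normal(0.0, config.pair_sd_log2, size=(n_genes, n_pairs))
    fold_shift = np.array([np.log2(planted.get(g, 1.0)) for g in genes])

    log2_wt = (
        baseline[:, None]
        + pair_effect
        + rng.normal(0.0, config.residual_sd_log2, size=(n_genes, n_pairs))
    )
    log2_mut = (
        baseline[:, None]
        + pair_effect
        + fold_shift[:, None]
        + rng.normal(0.0, config.residual_sd_log2, size=(n_genes, n_pairs))
    )
    mut_samples = [f"P{i + 1}_MUT" for i in range(n_pairs)]
    wt_samples = [f"P{i + 1}_WT" for i in range(n_pairs)]
    expression = pd.DataFrame(
        np.hstack([2.0**log2_mut, 2.0**log2_wt]),
        index=pd.Index(genes, name="gene"),
        columns=mut_samples + wt_samples,
    )
    tissues = ["atrial_septum" if i < 5 else "right_ventricle" for i in range(n_pairs)]
    pairs = pd.DataFrame(
        {
            "pair_id": [f"P{i + 1}" for i in range(n_pairs)],
            "mut_sample": mut_samples,
            "wt_sample": wt_samples,
            "tissue": tissues,
            "age_years": np.round(rng.uniform(0.1, 10.0, size=n_pairs), 1),
        }
    )
    truth = {"planted_folds": planted}
    return MatchedPairSet(pairs=pairs, expression=expression), truth


def simulate_densitometry(
    config: DensitometryConfig = DensitometryConfig(), seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Blot densitometry table with a planted genotype effect.

    log(band/GAPDH) = pair intercept + log(1 + effect) * [genotype == MUT]
    + N(0, noise_sd); GAPDH loading densities are log-normal around 1 and
    cancel exactly in the downstream model.
    """
    rng = np.random.default_rng(seed)
    rows = []
    beta = np.log1p(config.effect)
    for p in range(config.n_pairs):
        pair_intercept = rng.normal(0.0, config.pair_sd)
        for genotype in ("MUT", "WT"):
            for rep in range(config.n_replicates):
                gapdh = float(rng.lognormal(0.0, 0.2))
                log_ratio = (
                    pair_intercept
                    + (beta if genotype == "MUT" else 0.0)
                    + rng.normal(0.0, config.noise_sd)
                )
                rows.append(
                    {
                        "pair_id": f"pair{p + 1}",
                        "genotype": genotype,
                        "replicate": rep + 1,
                        "band": gapdh * float(np.exp(log_ratio)),
                        "gapdh": gapdh,
                    }
                )
    df = pd.DataFrame(rows)
    truth = {"percent_increase": 100.0 * config.effect, "beta_log": beta}
    return df, truth
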
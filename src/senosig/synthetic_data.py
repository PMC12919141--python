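"""Synthetic inputs with planted ground truth.

Three generators emulate the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without real data:

* :func:`simulate_catalog` — replicate-level log2 abundance matrices for a
  multi-induction senescence catalog (senescent vs proliferating arms per
  cell type and induction method), with proteins planted as cell-type
  members, cell-type-exclusive members, broadly shared "core" members, or
  single-induction (inconclusive) responders.
* :func:`simulate_cohort` — a participant-level cohort table with
  age-drifting senescence-associated protein (SAP) abundances, a latent
  sex-driven senescence burden, mediated cross-sectional outcomes, and
  left-truncated proportional-hazards event ages on the age time scale.
* :func:`simulate_tissue_atlas` — categorical immunohistochemistry-style
  expression levels per protein and tissue section, with sections matched
  to a signature's cell type enriched for medium/high levels.

All generators are bit-for-bit deterministic given their config and seed;
independent sub-streams are derived from one ``numpy.random.SeedSequence``
per call so adding a table never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPES_14",
    "ADULT_CELL_TYPES_9",
    "CatalogSimConfig",
    "CohortSimConfig",
    "TruthBundle",
    "CatalogData",
    "simulate_catalog",
    "simulate_cohort",
    "simulate_mediation_data",
    "simulate_tissue_atlas",
]

#: The 14 primary human cell types of the emulated senescence catalog.
CELL_TYPES_14 = (
    "renal_epithelial",
    "small_airway_epithelial",
    "skeletal_myoblast",
    "astrocyte",
    "osteoblast",
    "coronary_artery_endothelial",
    "preadipocyte",
    "vascular_smooth_muscle",
    "PBMC",
    "neonatal_keratinocyte",
    "neonatal_melanocyte",
    "umbilical_vein_endothelial",
    "neonatal_fibroblast",
    "fetal_lung_fibroblast",
)

#: Adult subset used for exclusive signatures (neonatal/fetal types excluded).
ADULT_CELL_TYPES_9 = CELL_TYPES_14[:9]

LEVELS = ("not detected", "low", "medium", "high")


@dataclass(frozen=True)
class CatalogSimConfig:
    """Configuration for the multi-induction catalog generator.

    Parameters
    ----------
    n_proteins
        Size of the protein universe.
    cell_types
        Cell-type labels (default: the 14 catalog cell types).
    inductions
        Senescence-induction labels. ``IR`` (ionizing radiation) plus at
        least one chemical inducer (etoposide ``ETO``, optionally ``DOXO``).
    n_replicates
        Replicates per condition arm.
    frac_exclusive
        Fraction of the universe planted as exclusive members *per* cell
        type (sets disjoint across cell types).
    frac_shared
        Fraction planted as members of a few (2-8) random cell types,
        emulating the broad overlap of senescence programs between cell
        types without reaching core breadth.
    n_core
        Number of proteins planted as members of at least ``core_breadth``
        cell types.
    core_breadth
        Minimum planted membership count for core proteins.
    frac_inconclusive
        Fraction planted as elevated in exactly one induction of one cell
        type (and hence classifiable only as inconclusive).
    effect_log2fc
        Mean planted log2 fold-change (senescent minus proliferating) in the
        qualifying inductions.
    noise_sd
        Replicate-level SD of log2 intensities.
    """

    n_proteins: int = 300
    cell_types: Sequence[str] = CELL_TYPES_14
    inductions: Sequence[str] = ("IR", "ETO")
    n_replicates: int = 4
    frac_exclusive: float = 0.015
    frac_shared: float = 0.15
    n_core: int = 30
    core_breadth: int = 9
    frac_inconclusive: float = 0.10
    effect_log2fc: float = 1.5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_replicates < 2:
            raise ValueError("n_proteins must be positive and n_replicates >= 2")
        for frac in (self.frac_exclusive, self.frac_shared, self.frac_inconclusive):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_core < 0:
            raise ValueError("n_core must be non-negative")
        if self.n_core and not 1 <= self.core_breadth <= len(self.cell_types):
            raise ValueError("core_breadth out of range")
        if "IR" not in self.inductions or len(self.inductions) < 2:
            raise ValueError("inductions must include IR and a chemical inducer")
        n_excl = int(round(self.frac_exclusive * self.n_proteins))
        planted = n_excl * len(self.cell_types) + self.n_core
        planted += int(round(self.frac_shared * self.n_proteins))
        planted += int(round(self.frac_inconclusive * self.n_proteins))
        if planted > self.n_proteins:
            raise ValueError("planted sets exceed the protein universe")


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration for the longitudinal-cohort generator.

    The cohort emulates a plasma-proteomics aging study: each participant
    carries a chronological age, a biological-age offset delta ~ N(0, tau),
    and a latent senescence burden ``m = a*sex + noise``. Planted SAP
    abundances drift with biological age (``sap_age_slope`` log2 units per
    year) and load on the burden; outcomes follow the mediation triangle
    sex -> burden -> outcome with coefficients ``(a, b, c_prime)``; event
    ages come from a Weibull proportional-hazards model on the age scale
    with delayed entry at the measurement age.
    """

    n_participants: int = 500
    age_range: tuple[float, float] = (22.0, 96.0)
    sex_balance: float = 0.5  # fraction male (sex coded 1)
    aging_offset_sd: float = 5.0  # tau, years
    sap_age_slope: float = 0.03  # log2 units / year of biological age
    burden_loading: float = 0.1  # log2 units per unit latent burden
    burden_noise_sd: float = 1.0
    abundance_noise_sd: float = 0.5
    mediation_coeffs: tuple[float, float, float] = (0.5, 0.8, 0.4)  # a, b, c'
    outcome_noise_sd: float = 1.0
    logit_intercept: float = -1.5
    hazard_log_hr: float = 0.5  # per SD of latent burden
    weibull_shape: float = 6.0
    weibull_scale: float = 85.0  # years
    censor_age: float = 95.0
    changepoint_age: float | None = None
    sex_changepoints: tuple[float, float] | None = None  # (female, male)
    changepoint_slope: float = 0.06  # extra log2/year during the ramp
    changepoint_ramp_half: float = 2.5  # ramp spans [cp - half, cp + half]
    n_changepoint_proteins: int = 50
    delta_trait_loading: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if not 0.0 <= self.sex_balance <= 1.0:
            raise ValueError("sex_balance must lie in [0, 1]")
        if self.aging_offset_sd < 0:
            raise ValueError("aging_offset_sd must be non-negative")


@dataclass
class TruthBundle:
    """Planted ground truth accompanying the synthetic tables."""

    sap_membership: dict[str, set[str]] = field(default_factory=dict)
    exclusive: dict[str, set[str]] = field(default_factory=dict)
    core: set[str] = field(default_factory=set)
    inconclusive: set[str] = field(default_factory=set)
    nonsap: set[str] = field(default_factory=set)
    proteins: list[str] = field(default_factory=list)
    # cohort-side truth (filled by simulate_cohort)
    delta: pd.Series | None = None
    burden: pd.Series | None = None
    planted_panel: list[str] = field(default_factory=list)
    changepoint_proteins: list[str] = field(default_factory=list)
    changepoint_ages: dict[str, float] = field(default_factory=dict)
    mediation_coeffs: tuple[float, float, float] | None = None
    hazard_log_hr: float | None = None

    @property
    def all_planted(self) -> set[str]:
        """Union of planted catalog members across cell types."""
        out: set[str] = set()
        for members in self.sap_membership.values():
            out |= members
        return out

    def to_json(self, path) -> None:
        payload = {
            "sap_membership": {c: sorted(s) for c, s in self.sap_membership.items()},
            "exclusive": {c: sorted(s) for c, s in self.exclusive.items()},
            "core": sorted(self.core),
            "inconclusive": sorted(self.inconclusive),
            "nonsap": sorted(self.nonsap),
            "proteins": list(self.proteins),
            "delta": None if self.delta is None else self.delta.to_dict(),
            "burden": None if self.burden is None else self.burden.to_dict(),
            "planted_panel": list(self.planted_panel),
            "changepoint_proteins": list(self.changepoint_proteins),
            "changepoint_ages": dict(self.changepoint_ages),
            "mediation_coeffs": self.mediation_coeffs,
            "hazard_log_hr": self.hazard_log_hr,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class CatalogData:
    """Replicate abundance matrices keyed by (cell type, induction).

    ``proliferating[key]`` and ``senescent[key]`` are protein x replicate
    DataFrames of log2 intensities with a shared protein index.
    """

    proliferating: dict[tuple[str, str], pd.DataFrame]
    senescent: dict[tuple[str, str], pd.DataFrame]

    @property
    def conditions(self) -> list[tuple[str, str]]:
        return list(self.proliferating)

    def save(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for (ct, ind), df in self.proliferating.items():
            df.to_csv(f"{outdir}/{ct}__{ind}__proliferating.tsv", sep="\t")
        for (ct, ind), df in self.senescent.items():
            df.to_csv(f"{outdir}/{ct}__{ind}__senescent.tsv", sep="\t")


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def simulate_catalog(config: CatalogSimConfig) -> tuple[CatalogData, TruthBundle]:
    """Generate replicate matrices for every (cell type, induction) condition.

    Planted members of a cell type are elevated by ``effect_log2fc`` in IR
    and in one randomly chosen chemical inducer for that cell type (so they
    qualify under the IR-plus-chemical rule); planted inconclusive proteins
    are elevated in IR only; all other proteins have expected log2FC = 0.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_plant, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))

    proteins = _protein_ids(config.n_proteins)
    pool = list(proteins)
    rng_plant.shuffle(pool)
    cursor = 0

    n_excl = int(round(config.frac_exclusive * config.n_proteins))
    exclusive: dict[str, set[str]] = {}
    membership: dict[str, set[str]] = {c: set() for c in config.cell_types}
    for ct in config.cell_types:
        exclusive[ct] = set(pool[cursor : cursor + n_excl])
        cursor += n_excl
        membership[ct] |= exclusive[ct]

    core = set(pool[cursor : cursor + config.n_core])
    cursor += config.n_core
    n_ct = len(config.cell_types)
    for prot in sorted(core):
        breadth = int(rng_plant.integers(config.core_breadth, n_ct + 1))
        idx = rng_plant.choice(n_ct, size=breadth, replace=False)
        for j in idx:
            membership[config.cell_types[j]].add(prot)

    n_shared = int(round(config.frac_shared * config.n_proteins))
    shared = set(pool[cursor : cursor + n_shared])
    cursor += n_shared
    shared_hi = min(8, max(2, n_ct - 1))
    for prot in sorted(shared):
        breadth = int(rng_plant.integers(2, shared_hi + 1))
        idx = rng_plant.choice(n_ct, size=breadth, replace=False)
        for j in idx:
            membership[config.cell_types[j]].add(prot)

    n_inc = int(round(config.frac_inconclusive * config.n_proteins))
    inconclusive = set(pool[cursor : cursor + n_inc])
    cursor += n_inc
    inc_cell = {
        p: config.cell_types[int(rng_plant.integers(n_ct))] for p in sorted(inconclusive)
    }

    planted_union = set().union(*membership.values()) if membership else set()
    nonsap = set(proteins) - planted_union - inconclusive

    chem = [i for i in config.inductions if i != "IR"]
    # per (protein, cell type): which inductions carry the planted effect
    elevated: dict[tuple[str, str], set[str]] = {}
    for ct in config.cell_types:
        for prot in sorted(membership[ct]):
            pick = chem[int(rng_plant.integers(len(chem)))]
            elevated[(prot, ct)] = {"IR", pick}
    for prot, ct in inc_cell.items():
        elevated[(prot, ct)] = {"IR"}

    base = rng_noise.normal(10.0, 2.0, size=config.n_proteins)
    base_s = pd.Series(base, index=proteins)

    pro_tabs: dict[tuple[str, str], pd.DataFrame] = {}
    sen_tabs: dict[tuple[str, str], pd.DataFrame] = {}
    reps = [f"rep{i + 1}" for i in range(config.n_replicates)]
    for ct in config.cell_types:
        for ind in config.inductions:
            shift = np.array(
                [
                    config.effect_log2fc
                    if ind in elevated.get((p, ct), ())
                    else 0.0
                    for p in proteins
                ]
            )
            noise_pro = rng_noise.normal(
                0.0, config.noise_sd, size=(config.n_proteins, config.n_replicates)
            )
            noise_sen = rng_noise.normal(
                0.0, config.noise_sd, size=(config.n_proteins, config.n_replicates)
            )
            pro_tabs[(ct, ind)] = pd.DataFrame(
                base_s.to_numpy()[:, None] + noise_pro, index=proteins, columns=reps
            )
            sen_tabs[(ct, ind)] = pd.DataFrame(
                base_s.to_numpy()[:, None] + shift[:, None] + noise_sen,
                index=proteins,
                columns=reps,
            )

    truth = TruthBundle(
        sap_membership={c: set(s) for c, s in membership.items()},
        exclusive=exclusive,
        core=core,
        inconclusive=inconclusive,
        nonsap=nonsap,
        proteins=proteins,
    )
    return CatalogData(pro_tabs, sen_tabs), truth


def simulate_cohort(
    config: CohortSimConfig, truth: TruthBundle
) -> tuple[pd.DataFrame, TruthBundle]:
    """Generate a participant-level cohort aligned with the catalog truth.

    Returns the cohort table (covariates, traits, survival columns, protein
    abundances) and the truth bundle updated with per-participant delta,
    latent burden, the planted signal panel, and the planted effect sizes.
    """
    planted = sorted(truth.all_planted)
    if not planted:
        raise ValueError(
            "catalog truth has no planted members; mediation/hazard signal "
            "cannot be planted in the cohort"
        )
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(6)
    rng_cov, rng_bio, rng_prot, rng_out, rng_surv, _ = (
        np.random.default_rng(s) for s in streams
    )
    n = config.n_participants
    pid = [f"PT{i:05d}" for i in range(n)]

    lo, hi = config.age_range
    age = rng_cov.uniform(lo, hi, size=n)
    sex = (rng_cov.uniform(size=n) < config.sex_balance).astype(np.int8)
    race = rng_cov.choice(["A", "B", "C"], size=n, p=[0.6, 0.3, 0.1])

    delta = rng_bio.normal(0.0, config.aging_offset_sd, size=n)
    bio_age = age + delta
    a, b, c_prime = config.mediation_coeffs
    burden = a * sex + rng_bio.normal(0.0, config.burden_noise_sd, size=n)

    proteins = list(truth.proteins) if truth.proteins else planted
    cp_prots = planted[: config.n_changepoint_proteins] if (
        config.changepoint_age is not None or config.sex_changepoints is not None
    ) else []
    cp_ages: dict[str, float] = {}
    if config.sex_changepoints is not None:
        cp_f, cp_m = config.sex_changepoints
        cp_by_subject = np.where(sex == 1, cp_m, cp_f)
        cp_ages = {"F": cp_f, "M": cp_m}
    elif config.changepoint_age is not None:
        cp_by_subject = np.full(n, config.changepoint_age)
        cp_ages = {"pooled": config.changepoint_age}
    else:
        cp_by_subject = None

    planted_set = set(planted)
    cp_set = set(cp_prots)
    base = rng_prot.normal(10.0, 1.0, size=len(proteins))
    X = base[None, :] + rng_prot.normal(
        0.0, config.abundance_noise_sd, size=(n, len(proteins))
    )
    half = config.changepoint_ramp_half
    for j, prot in enumerate(proteins):
        if prot in planted_set:
            X[:, j] += config.sap_age_slope * bio_age + config.burden_loading * burden
        if prot in cp_set and cp_by_subject is not None:
            # piecewise-linear ramp centered at the change point: baseline
            # slope, an elevated slope for +-half years, baseline again
            ramp = np.clip(age - (cp_by_subject - half), 0.0, 2.0 * half)
            X[:, j] += config.changepoint_slope * ramp

    # cross-sectional outcomes on the mediation triangle sex -> burden -> y
    frailty = b * burden + c_prime * sex + rng_out.normal(
        0.0, config.outcome_noise_sd, size=n
    )
    eta = config.logit_intercept + b * burden + c_prime * sex
    diabetes = (rng_out.uniform(size=n) < 1.0 / (1.0 + np.exp(-eta))).astype(np.int8)
    lean_mass = (
        50.0
        - config.delta_trait_loading * delta
        - 0.05 * age
        + rng_out.normal(0.0, 1.0, size=n)
    )
    walking_pace = (
        1.6 - 0.15 * burden - 0.005 * age + rng_out.normal(0.0, 0.2, size=n)
    )

    # survival: Weibull PH on the age scale, conditional on survival to entry
    z = (burden - burden.mean()) / burden.std(ddof=1)
    hr = np.exp(config.hazard_log_hr * z)
    u = rng_surv.uniform(size=n)
    shape, scale = config.weibull_shape, config.weibull_scale
    t_event = scale * ((age / scale) ** shape - np.log(u) / hr) ** (1.0 / shape)
    status = (t_event <= config.censor_age).astype(np.int8)
    exit_age = np.minimum(t_event, config.censor_age)
    # administrative censoring exactly at entry would give a zero-length record
    exit_age = np.maximum(exit_age, age + 1e-6)

    cohort = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "race": race,
            "frailty": frailty,
            "diabetes": diabetes,
            "lean_mass": lean_mass,
            "walking_pace": walking_pace,
            "entry_age": age,
            "exit_age": exit_age,
            "event_status": status,
        },
        index=pd.Index(pid, name="participant"),
    )
    cohort = pd.concat(
        [cohort, pd.DataFrame(X, index=cohort.index, columns=proteins)], axis=1
    )

    out = truth  # updated in place so catalog- and cohort-side truth stay together
    out.delta = pd.Series(delta, index=cohort.index, name="delta")
    out.burden = pd.Series(burden, index=cohort.index, name="burden")
    out.planted_panel = planted
    out.changepoint_proteins = cp_prots
    out.changepoint_ages = cp_ages
    out.mediation_coeffs = config.mediation_coeffs
    out.hazard_log_hr = config.hazard_log_hr
    return cohort, out


def simulate_mediation_data(
    n: int,
    a: float,
    b: float,
    c_prime: float,
    mediator_noise_sd: float = 1.0,
    outcome_noise_sd: float = 1.0,
    family: str = "gaussian",
    seed: int = 0,
) -> pd.DataFrame:
    """Minimal exposure/mediator/outcome triple for mediation checks.

    ``mediator = a*exposure + e_m``; gaussian outcome
    ``y = b*mediator + c_prime*exposure + e_y``; binomial outcome uses the
    same linear predictor through a logit link. In the gaussian,
    vanishing-noise limit the proportion mediated is ``ab / (ab + c')``.
    """
    rng = np.random.default_rng(seed)
    exposure = rng.integers(0, 2, size=n).astype(float)
    mediator = a * exposure + rng.normal(0.0, mediator_noise_sd, size=n)
    eta = b * mediator + c_prime * exposure
    if family == "gaussian":
        outcome = eta + rng.normal(0.0, outcome_noise_sd, size=n)
    elif family == "binomial":
        outcome = (rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-(eta - eta.mean())))).astype(
            float
        )
    else:
        raise ValueError(f"unknown family {family!r}")
    return pd.DataFrame({"exposure": exposure, "mediator": mediator, "outcome": outcome})


def simulate_tissue_atlas(
    signatures: Mapping[str, set[str] | Sequence[str]],
    seed: int = 0,
    enrichment: float = 0.5,
    n_unmatched_sections: int = 6,
) -> pd.DataFrame:
    """Categorical expression levels per protein and tissue section.

    One "matched" section is generated per signature plus
    ``n_unmatched_sections`` generic sections. In a matched section the
    proteins of its signature have their level distribution shifted toward
    medium/high by ``enrichment`` (0 = no shift, 1 = fully shifted).

    Returns a long DataFrame with columns ``protein``, ``section``,
    ``level`` (one of ``"not detected"``, ``"low"``, ``"medium"``,
    ``"high"``).
    """
    if not signatures:
        raise ValueError("at least one signature is required")
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment must lie in [0, 1]")
    sigs = {name: set(members) for name, members in signatures.items()}
    if any(len(s) == 0 for s in sigs.values()):
        raise ValueError("empty signature set")
    proteins = sorted(set().union(*sigs.values()))
    base = np.array([0.45, 0.25, 0.20, 0.10])
    target = np.array([0.05, 0.10, 0.35, 0.50])
    enriched = (1.0 - enrichment) * base + enrichment * target

    rng = np.random.default_rng(seed)
    sections = [f"{name}_matched" for name in sorted(sigs)] + [
        f"other_{i + 1}" for i in range(n_unmatched_sections)
    ]
    rows = []
    for section in sections:
        sig_name = section[: -len("_matched")] if section.endswith("_matched") else None
        members = sigs.get(sig_name, set())
        for prot in proteins:
            probs = enriched if prot in members else base
            level = LEVELS[int(rng.choice(4, p=probs))]
            rows.append((prot, section, level))
    return pd.DataFrame(rows, columns=["protein", "section", "level"])
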
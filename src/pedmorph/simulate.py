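"""Synthetic pedigrees, genotypes, morphs, and quantitative colour traits.

The generator mirrors the breeding design the analyses assume: a founder
cohort of sires and dams, each dam mated to a few sires, clutches of
offspring with Mendelian genotype transmission (honouring ZW transmission
for Z-linked models), morphs read off genotypes, and additive-genetic plus
residual variation in colour proportions simulated on the
arcsine-square-root scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .mendelian import (
    GeneticModel,
    Genotype,
    ZygosityAssumption,
    model3,
    parental_genotype_distribution,
    phenotype_of,
)
from .pedigree import MORPHS, Individual, Pedigree
from .phenotype import ExpressionThresholds, arcsin_sqrt

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_pedigree",
    "simulate_quantitative",
    "simulate_parent_offspring",
    "resample_offspring_morphs",
    "make_paper_like_fixture",
]

#: default morph-conditional means of colour proportions (pre-transform),
#: in the 20-60 % coverage range typical of expressing throats
DEFAULT_TRAIT_MEANS = {"orange": 0.35, "yellow": 0.40}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic breeding design."""

    model: GeneticModel = field(default_factory=model3)
    allele_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "orange": {"O": 0.4, "o": 0.6},
            "yellow": {"Y": 0.4, "y": 0.6},
        }
    )
    founder_morph_probs: Optional[Mapping[str, float]] = None
    founder_zygosity: str = "hwe"  # "hwe" | "equal" (with founder_morph_probs)
    n_sires: int = 23
    n_dams: int = 17
    #: fractional values randomize between floor and ceil per dam
    matings_per_dam: float = 1.5
    mean_clutch_size: float = 2.3
    sex_ratio: float = 0.55  # fraction of male offspring
    h2: Mapping[str, float] = field(
        default_factory=lambda: {"orange": 0.5, "yellow": 0.5}
    )
    phenotypic_variance: float = 0.02  # on the transformed scale
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    female_scaling: Mapping[str, float] = field(
        default_factory=lambda: {"orange": 2.0 / 3.0, "yellow": 0.5}
    )
    thresholds: ExpressionThresholds = field(default_factory=ExpressionThresholds)
    n_cohorts: int = 2

    def __post_init__(self) -> None:
        for trait, value in self.h2.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"h2[{trait}]={value} outside [0, 1]")
        if self.phenotypic_variance <= 0:
            raise ValueError("phenotypic_variance must be positive")
        if self.mean_clutch_size < 1:
            raise ValueError("mean_clutch_size must be >= 1")


@dataclass
class SimulatedTruth:
    """Ground truth: genotypes and breeding values per individual."""

    model: str
    genotypes: Dict[str, Genotype]
    breeding_values: Dict[str, Dict[str, float]]
    config: SimulationConfig


def _draw_founder_genotype(
    config: SimulationConfig, sex: str, rng: np.random.Generator
) -> Genotype:
    model = config.model
    hemizygous = model.linkage == "z_linked" and sex == "female"
    if config.founder_morph_probs is not None:
        morphs = list(config.founder_morph_probs)
        probs = np.array([config.founder_morph_probs[m] for m in morphs], float)
        probs = probs / probs.sum()
        morph = morphs[rng.choice(len(morphs), p=probs)]
        scheme = ZygosityAssumption(
            "equal" if config.founder_zygosity == "equal" else "hwe",
            allele_freqs=config.allele_freqs,
        )
        dist = parental_genotype_distribution(morph, sex, model, scheme)
        genotypes = list(dist)
        weights = np.array([dist[g] for g in genotypes])
        return genotypes[rng.choice(len(genotypes), p=weights)]
    loci_states: List[Tuple[str, ...]] = []
    for locus in model.loci:
        alleles = list(config.allele_freqs[locus.name])
        probs = np.array(
            [config.allele_freqs[locus.name][a] for a in alleles], float
        )
        probs = probs / probs.sum()
        k = 1 if hemizygous else 2
        draw = [alleles[rng.choice(len(alleles), p=probs)] for _ in range(k)]
        loci_states.append(tuple(sorted(draw)) if k == 2 else (draw[0],))
    return tuple(loci_states)


def _transmit(
    sire_genotype: Genotype,
    dam_genotype: Genotype,
    sex: str,
    model: GeneticModel,
    rng: np.random.Generator,
) -> Genotype:
    """Mendelian transmission; ZW: daughters get a paternal Z only."""
    loci_states: List[Tuple[str, ...]] = []
    for s_pair, d_pair in zip(sire_genotype, dam_genotype):
        paternal = s_pair[rng.integers(len(s_pair))]
        if model.linkage == "z_linked":
            if sex == "female":
                loci_states.append((paternal,))
                continue
            maternal = d_pair[0]
        else:
            maternal = d_pair[rng.integers(len(d_pair))]
        loci_states.append(tuple(sorted((paternal, maternal))))
    return tuple(loci_states)


def simulate_pedigree(
    config: SimulationConfig, seed: int = 0
) -> Tuple[Pedigree, SimulatedTruth]:
    """Generate a two-generation pedigree with genotypes and morphs.

    Founder genotypes are drawn from allele frequencies at HWE (or from
    morph probabilities with the requested founder zygosity scheme);
    offspring genotypes follow Mendelian segregation. Deterministic under a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    model = config.model
    pedigree = Pedigree()
    genotypes: Dict[str, Genotype] = {}

    sires = [f"S{k:03d}" for k in range(1, config.n_sires + 1)]
    dams = [f"D{k:03d}" for k in range(1, config.n_dams + 1)]
    for sid in sires:
        g = _draw_founder_genotype(config, "male", rng)
        genotypes[sid] = g
        pedigree.add(
            Individual(sid, sex="male", generation="F0", cohort="founder",
                       morph=phenotype_of(g, model))
        )
    for did in dams:
        g = _draw_founder_genotype(config, "female", rng)
        genotypes[did] = g
        pedigree.add(
            Individual(did, sex="female", generation="F0", cohort="founder",
                       morph=phenotype_of(g, model))
        )

    cohorts = [f"season-{k + 1}" for k in range(config.n_cohorts)]
    offspring_counter = 0
    clutch_counter = 0
    for did in dams:
        base = int(math.floor(config.matings_per_dam))
        frac = config.matings_per_dam - base
        n_matings = base + (1 if rng.random() < frac else 0)
        if n_matings == 0:
            continue
        chosen = rng.choice(
            len(sires), size=min(n_matings, len(sires)), replace=False
        )
        for j in chosen:
            sid = sires[int(j)]
            clutch_counter += 1
            clutch = f"C{clutch_counter:03d}"
            cohort = cohorts[int(rng.integers(len(cohorts)))]
            size = 1 + rng.poisson(max(config.mean_clutch_size - 1.0, 0.0))
            for _ in range(size):
                offspring_counter += 1
                oid = f"O{offspring_counter:04d}"
                sex = "male" if rng.random() < config.sex_ratio else "female"
                g = _transmit(genotypes[sid], genotypes[did], sex, model, rng)
                genotypes[oid] = g
                pedigree.add(
                    Individual(
                        oid,
                        sex=sex,
                        generation="F1",
                        cohort=cohort,
                        clutch_id=clutch,
                        sire_id=sid,
                        dam_id=did,
                        morph=phenotype_of(g, model),
                    )
                )
    truth = SimulatedTruth(model.name, genotypes, {}, config)
    return pedigree, truth


def _morph_expresses(morph: str, trait: str) -> bool:
    if trait == "orange":
        return morph in ("O", "OY")
    return morph in ("Y", "OY")


def simulate_quantitative(
    pedigree: Pedigree,
    truth: SimulatedTruth,
    config: SimulationConfig,
    seed: int = 0,
) -> None:
    """Attach colour proportions with additive genetics to a pedigree.

    Breeding values flow founder -> offspring with Mendelian-sampling
    variance Va/2; phenotypes are built on the transformed scale
    (morph-conditional mean + breeding value + residual), back-transformed
    via sin^2, scaled down in females, and floored at the expression
    threshold for expressing morphs so labels stay consistent. Mutates the
    pedigree in place and records breeding values in ``truth``.
    """
    rng = np.random.default_rng(seed)
    vp = config.phenotypic_variance
    order = pedigree.topological_order()
    thresholds = config.thresholds

    bv_all: Dict[str, Dict[str, float]] = {}
    raw: Dict[str, Dict[str, float]] = {t: {} for t in ("orange", "yellow")}
    for trait in ("orange", "yellow"):
        h2 = config.h2.get(trait, 0.5)
        va = h2 * vp
        ve = (1.0 - h2) * vp
        bv: Dict[str, float] = {}
        for ind_id in order:
            ind = pedigree[ind_id]
            if ind.sire_id is None or ind.dam_id is None:
                bv[ind_id] = rng.normal(0.0, math.sqrt(va)) if va > 0 else 0.0
            else:
                mid = 0.5 * (bv[ind.sire_id] + bv[ind.dam_id])
                deviate = rng.normal(0.0, math.sqrt(0.5 * va)) if va > 0 else 0.0
                bv[ind_id] = mid + deviate
        bv_all[trait] = bv
        mean_t = arcsin_sqrt(config.trait_means.get(trait, DEFAULT_TRAIT_MEANS[trait]))
        for ind_id in order:
            ind = pedigree[ind_id]
            morph = ind.morph
            if morph is None:
                continue
            stage = "juvenile" if ind.generation != "F0" else "adult"
            floor = thresholds.minimum(trait, stage)
            if not _morph_expresses(morph, trait):
                raw[trait][ind_id] = float(rng.uniform(0.0, 0.5 * floor))
                continue
            t_value = mean_t + bv[ind_id] + (
                rng.normal(0.0, math.sqrt(ve)) if ve > 0 else 0.0
            )
            t_value = min(max(t_value, 0.0), math.pi / 2)
            prop = math.sin(t_value) ** 2
            if ind.sex == "female":
                prop *= config.female_scaling.get(trait, 1.0)
            raw[trait][ind_id] = max(prop, floor)

    truth.breeding_values = bv_all
    for ind_id in order:
        ind = pedigree[ind_id]
        if ind.morph is None:
            continue
        po = raw["orange"][ind_id]
        py = raw["yellow"][ind_id]
        if po + py > 1.0:  # cap joint coverage, preserving the ratio
            scale = 1.0 / (po + py)
            po *= scale
            py *= scale
        ind.prop_orange = po
        ind.prop_yellow = py


def resample_offspring_morphs(
    pedigree: Pedigree,
    model: GeneticModel,
    assumption: ZygosityAssumption,
    rng: np.random.Generator,
) -> None:
    """Redraw each offspring's morph from its mating's expected mixture.

    This generates data from exactly the per-offspring mixture model the
    expected-frequency G test assumes (no zygosity persistence across
    siblings), which is the appropriate null for model-selection
    calibration. Mutates the pedigree in place; parents are untouched.
    """
    from .mendelian import cross as _cross

    cache: Dict[Tuple[str, str], Dict[str, Dict[str, float]]] = {}
    for ind in pedigree:
        if ind.is_founder or ind.sire_id is None or ind.dam_id is None:
            continue
        sire = pedigree[ind.sire_id]
        dam = pedigree[ind.dam_id]
        if sire.morph is None or dam.morph is None:
            continue
        key = (sire.morph, dam.morph)
        if key not in cache:
            sire_dist = parental_genotype_distribution(
                sire.morph, "male", model, assumption,
                prop_orange=sire.prop_orange, prop_yellow=sire.prop_yellow,
            )
            dam_dist = parental_genotype_distribution(
                dam.morph, "female", model, assumption,
                prop_orange=dam.prop_orange, prop_yellow=dam.prop_yellow,
            )
            cache[key] = _cross(sire_dist, dam_dist, model)
        sex = ind.sex if ind.sex in ("male", "female") else "unknown"
        vec = cache[key][sex]
        probs = np.array([vec[m] for m in MORPHS])
        ind.morph = MORPHS[int(rng.choice(len(MORPHS), p=probs / probs.sum()))]


def simulate_parent_offspring(
    n_families: int,
    h2: float,
    rng: np.random.Generator,
    n_offspring: int = 2,
    vp: float = 1.0,
) -> Dict[str, np.ndarray]:
    """Vectorized additive-model families for regression identity checks.

    Returns arrays ``sire``, ``dam``, ``midparent`` and ``midoffspring``
    (mean over ``n_offspring`` offspring) of phenotypes P = A + E with
    var(A) = h2*vp.
    """
    if not (0.0 <= h2 <= 1.0):
        raise ValueError("h2 outside [0, 1]")
    va, ve = h2 * vp, (1.0 - h2) * vp
    a_sire = rng.normal(0.0, math.sqrt(va), n_families)
    a_dam = rng.normal(0.0, math.sqrt(va), n_families)
    p_sire = a_sire + rng.normal(0.0, math.sqrt(ve), n_families)
    p_dam = a_dam + rng.normal(0.0, math.sqrt(ve), n_families)
    mid_a = 0.5 * (a_sire + a_dam)
    kids = (
        mid_a[:, None]
        + rng.normal(0.0, math.sqrt(0.5 * va), (n_families, n_offspring))
        + rng.normal(0.0, math.sqrt(ve), (n_families, n_offspring))
    )
    return {
        "sire": p_sire,
        "dam": p_dam,
        "midparent": 0.5 * (p_sire + p_dam),
        "midoffspring": kids.mean(axis=1),
    }


# ---------------------------------------------------------------------------
# Study-shaped fixture

# parental and offspring morph tallies of the emulated breeding design,
# keyed (group, sex) -> {morph: count}
_FIXTURE_COUNTS = {
    ("parental", "male"): {"G": 7, "O": 4, "OY": 8, "Y": 4},      # 23 sires
    ("parental", "female"): {"G": 2, "O": 5, "OY": 6, "Y": 4},    # 17 dams
    ("cohort1", "male"): {"G": 5, "O": 7, "OY": 2, "Y": 9},       # 23
    ("cohort1", "female"): {"G": 5, "O": 4, "OY": 5, "Y": 2},     # 16
    ("cohort2", "male"): {"G": 1, "O": 5, "OY": 2, "Y": 1},       # 9
    ("cohort2", "female"): {"G": 1, "O": 2, "OY": 3, "Y": 1},     # 7
    ("cohort2", "unknown"): {"G": 0, "O": 3, "OY": 0, "Y": 0},    # 3
}
_FIXTURE_COHORTS = {"cohort1": "2012-2013", "cohort2": "2013-2014"}


def _draw_props_for_morph(
    morph: str,
    stage: str,
    thresholds: ExpressionThresholds,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    def above(trait: str) -> float:
        lo = thresholds.minimum(trait, stage)
        return float(rng.uniform(max(lo, 0.05), 0.45))

    def below(trait: str) -> float:
        return float(rng.uniform(0.0, 0.5 * thresholds.minimum(trait, stage)))

    po = above("orange") if morph in ("O", "OY") else below("orange")
    py = above("yellow") if morph in ("Y", "OY") else below("yellow")
    if po + py > 1.0:
        scale = 0.99 / (po + py)
        po, py = po * scale, py * scale
    return po, py


def make_paper_like_fixture(seed: int = 0) -> Pedigree:
    """Deterministic pedigree shaped like the emulated breeding study.

    23 sires and 17 dams with fixed morph tallies, 25 clutches, and 58
    offspring split over two season cohorts with fixed per-sex morph
    tallies. Sire-dam pairings are synthetic (the real pairing table is
    not published), so pairing-dependent statistics are not reproduced.
    """
    rng = np.random.default_rng(seed)
    thresholds = ExpressionThresholds()
    pedigree = Pedigree()

    def expand(group: str, sex: str) -> List[str]:
        counts = _FIXTURE_COUNTS[(group, sex)]
        morphs: List[str] = []
        for morph in MORPHS:
            morphs.extend([morph] * counts.get(morph, 0))
        return morphs

    sire_morphs = expand("parental", "male")
    dam_morphs = expand("parental", "female")
    sires, dams = [], []
    for k, morph in enumerate(sire_morphs, start=1):
        sid = f"S{k:03d}"
        po, py = _draw_props_for_morph(morph, "adult", thresholds, rng)
        pedigree.add(
            Individual(sid, sex="male", generation="F0", cohort="founder",
                       prop_orange=po, prop_yellow=py, morph=morph)
        )
        sires.append(sid)
    for k, morph in enumerate(dam_morphs, start=1):
        did = f"D{k:03d}"
        po, py = _draw_props_for_morph(morph, "adult", thresholds, rng)
        pedigree.add(
            Individual(did, sex="female", generation="F0", cohort="founder",
                       prop_orange=po, prop_yellow=py, morph=morph)
        )
        dams.append(did)

    # 25 clutches: every dam once, 8 dams twice; sires cycle so 23 are used
    clutch_parents: List[Tuple[str, str]] = []
    dam_cycle = dams + dams[:8]
    for k in range(25):
        clutch_parents.append((sires[k % len(sires)], dam_cycle[k]))

    offspring_specs: List[Tuple[str, str, str]] = []  # (cohort, sex, morph)
    for group in ("cohort1", "cohort2"):
        for sex in ("male", "female", "unknown"):
            if (group, sex) not in _FIXTURE_COUNTS:
                continue
            for morph in expand(group, sex):
                offspring_specs.append((_FIXTURE_COHORTS[group], sex, morph))
    perm = rng.permutation(len(offspring_specs))

    cohort1_clutches = list(range(16))
    cohort2_clutches = list(range(16, 25))
    used_cohort1 = used_cohort2 = 0
    for n, idx in enumerate(perm, start=1):
        cohort, sex, morph = offspring_specs[int(idx)]
        if cohort == _FIXTURE_COHORTS["cohort1"]:
            clutch_idx = cohort1_clutches[used_cohort1 % len(cohort1_clutches)]
            used_cohort1 += 1
        else:
            clutch_idx = cohort2_clutches[used_cohort2 % len(cohort2_clutches)]
            used_cohort2 += 1
        sire_id, dam_id = clutch_parents[clutch_idx]
        po, py = _draw_props_for_morph(morph, "juvenile", thresholds, rng)
        pedigree.add(
            Individual(
                f"O{n:04d}",
                sex=sex,
                generation="F1",
                cohort=cohort,
                clutch_id=f"C{clutch_idx + 1:03d}",
                sire_id=sire_id,
                dam_id=dam_id,
                prop_orange=po,
                prop_yellow=py,
                morph=morph,
            )
        )
    pedigree.validate()
    return pedigree
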
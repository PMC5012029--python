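"""Candidate Mendelian architectures for a four-morph colour polymorphism.

Three models are supported, each autosomal or Z-linked (ZW system, females
hemizygous):

* ``model1`` — one locus, four alleles, one per morph (phenotype of
  heterozygotes requires an explicit dominance order);
* ``model2`` — one locus, three alleles O/Y/G with co-dominant O and Y
  (OO, OG -> orange; YY, YG -> yellow; OY -> orange+yellow; GG -> grey);
* ``model3`` — two loci, 'orange' (O dominant over o) and 'yellow'
  (Y dominant over y); presence of a dominant allele expresses the colour.

Parents whose phenotype does not pin down zygosity get a genotype
distribution under one of three assumption schemes (equal 50:50, HWE from
estimated allele frequencies, or a deterministic expression threshold), and
expected offspring morph frequencies over a pedigree are compared to
observed ones with a likelihood-ratio G test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .pedigree import MORPHS, Individual, MorphCounts, Pedigree
from .phenotype import ExpressionThresholds, effective_yellow, is_expressed

logger = logging.getLogger(__name__)

__all__ = [
    "LocusSpec",
    "GeneticModel",
    "model1",
    "model2",
    "model3",
    "ZygosityAssumption",
    "GTestResult",
    "ModelFitResult",
    "ExclusionReport",
    "genotype_space",
    "phenotype_of",
    "parental_genotype_distribution",
    "estimate_allele_frequencies",
    "cross",
    "expected_offspring_frequencies",
    "g_test",
    "fit_all_models",
    "model1_exclusion",
    "zlinked_exclusion",
    "reference_expression_means",
]

# A genotype is a tuple with one entry per locus; each entry is a sorted
# 2-tuple of allele symbols (diploid) or a 1-tuple (hemizygous female under
# Z linkage).
Genotype = Tuple[Tuple[str, ...], ...]
GenotypeDistribution = Dict[Genotype, float]


@dataclass(frozen=True)
class LocusSpec:
    name: str
    alleles: Tuple[str, ...]


@dataclass(frozen=True)
class GeneticModel:
    name: str
    linkage: str  # "autosomal" | "z_linked"
    loci: Tuple[LocusSpec, ...]
    dominance_order: Optional[Tuple[str, ...]] = None  # model1 only

    def __post_init__(self) -> None:
        if self.linkage not in ("autosomal", "z_linked"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


def model1(
    linkage: str = "autosomal",
    dominance_order: Optional[Sequence[str]] = None,
) -> GeneticModel:
    """One locus, four alleles named after the morphs."""
    return GeneticModel(
        name="model1",
        linkage=linkage,
        loci=(LocusSpec("morph", ("O", "Y", "OY", "G")),),
        dominance_order=tuple(dominance_order) if dominance_order else None,
    )


def model2(linkage: str = "autosomal") -> GeneticModel:
    """One locus, three alleles with co-dominant O/Y expression."""
    return GeneticModel(
        name="model2", linkage=linkage, loci=(LocusSpec("colour", ("O", "Y", "G")),)
    )


def model3(linkage: str = "autosomal") -> GeneticModel:
    """Two loci, dominant presence alleles for orange and yellow."""
    return GeneticModel(
        name="model3",
        linkage=linkage,
        loci=(LocusSpec("orange", ("O", "o")), LocusSpec("yellow", ("Y", "y"))),
    )


def get_model(name: str, linkage: str = "autosomal") -> GeneticModel:
    factories = {"model1": model1, "model2": model2, "model3": model3}
    if name not in factories:
        raise ValueError(f"unknown model {name!r}")
    return factories[name](linkage)


# ---------------------------------------------------------------------------
# Genotype enumeration and phenotype mapping


def _is_hemizygous(model: GeneticModel, sex: str) -> bool:
    return model.linkage == "z_linked" and sex == "female"


def genotype_space(model: GeneticModel, sex: str = "male") -> List[Genotype]:
    """All genotypes for an individual of ``sex`` under ``model``."""
    per_locus: List[List[Tuple[str, ...]]] = []
    for locus in model.loci:
        if _is_hemizygous(model, sex):
            per_locus.append([(a,) for a in locus.alleles])
        else:
            per_locus.append(
                [tuple(sorted(pair)) for pair in combinations_with_replacement(locus.alleles, 2)]
            )
    return [tuple(combo) for combo in product(*per_locus)]


def phenotype_of(genotype: Genotype, model: GeneticModel) -> str:
    """Map a genotype onto a morph in {O, Y, OY, G}; total function."""
    if model.name == "model3":
        orange = "O" in genotype[0]
        yellow = "Y" in genotype[1]
        if orange and yellow:
            return "OY"
        if orange:
            return "O"
        if yellow:
            return "Y"
        return "G"
    if model.name == "model2":
        alleles = set(genotype[0])
        if {"O", "Y"} <= alleles:
            return "OY"
        if "O" in alleles:
            return "O"
        if "Y" in alleles:
            return "Y"
        return "G"
    # model1: allele symbols are morph names
    alleles = genotype[0]
    if len(set(alleles)) == 1:
        return alleles[0]
    if model.dominance_order is None:
        raise ValueError(
            "model1 heterozygote phenotype requires an explicit dominance_order"
        )
    rank = {a: i for i, a in enumerate(model.dominance_order)}
    return min(alleles, key=lambda a: rank[a])


# ---------------------------------------------------------------------------
# Parental zygosity assumptions


@dataclass(frozen=True)
class ZygosityAssumption:
    """Scheme assigning genotype probabilities to ambiguous parents.

    ``equal`` — 50:50 homozygous/heterozygous per ambiguous locus;
    ``hwe`` — conditional HWE genotype frequencies (requires
    ``allele_freqs``, a per-locus mapping allele -> frequency);
    ``threshold`` — homozygote iff the individual's effective colour
    proportion strictly exceeds the reference mean (requires
    ``reference_means``: trait -> mean or trait -> {sex: mean}).
    """

    scheme: str = "equal"
    allele_freqs: Optional[Mapping[str, Mapping[str, float]]] = None
    reference_means: Optional[Mapping[str, object]] = None

    def __post_init__(self) -> None:
        if self.scheme not in ("equal", "hwe", "threshold"):
            raise ValueError(f"unknown zygosity scheme {self.scheme!r}")

    def ref_mean(self, trait: str, sex: str) -> float:
        if self.reference_means is None or trait not in self.reference_means:
            raise ValueError(
                f"threshold scheme requires a reference mean for {trait!r}"
            )
        entry = self.reference_means[trait]
        if isinstance(entry, Mapping):
            if sex in entry:
                return float(entry[sex])
            return float(next(iter(entry.values())))
        return float(entry)


def _hwe_genotype_prob(
    pair: Tuple[str, ...], freqs: Mapping[str, float]
) -> float:
    if len(pair) == 1:
        return freqs[pair[0]]
    a, b = pair
    if a == b:
        return freqs[a] ** 2
    return 2.0 * freqs[a] * freqs[b]


def parental_genotype_distribution(
    morph: str,
    sex: str,
    model: GeneticModel,
    assumption: ZygosityAssumption,
    prop_orange: Optional[float] = None,
    prop_yellow: Optional[float] = None,
) -> GenotypeDistribution:
    """Genotype distribution for a parent of known morph.

    Supported only on genotypes whose phenotype equals ``morph``; fully
    determined phenotypes get probability one regardless of scheme.
    """
    if morph not in MORPHS:
        raise ValueError(f"unknown morph {morph!r}")
    candidates = [
        g for g in genotype_space(model, sex) if phenotype_of(g, model) == morph
    ]
    if not candidates:
        raise ValueError(
            f"morph {morph!r} is impossible for a {sex} under "
            f"{model.name}/{model.linkage}"
        )
    if len(candidates) == 1:
        return {candidates[0]: 1.0}

    if assumption.scheme == "equal":
        # each ambiguous locus has exactly two candidate states
        # (homozygous-dominant vs heterozygous), so uniform == per-locus 50:50
        p = 1.0 / len(candidates)
        return {g: p for g in candidates}

    if assumption.scheme == "hwe":
        if assumption.allele_freqs is None:
            raise ValueError("hwe scheme requires allele_freqs")
        weights = []
        for g in candidates:
            w = 1.0
            for locus, pair in zip(model.loci, g):
                w *= _hwe_genotype_prob(pair, assumption.allele_freqs[locus.name])
            weights.append(w)
        total = float(sum(weights))
        if total <= 0:
            raise ValueError(
                f"allele frequencies give zero mass to morph {morph!r} genotypes"
            )
        return {g: w / total for g, w in zip(candidates, weights)}

    # threshold scheme: deterministic per-locus homo/het call
    if prop_orange is None or prop_yellow is None:
        raise ValueError(
            "threshold scheme requires the parent's colour proportions"
        )
    eff = {
        "orange": prop_orange,
        "yellow": effective_yellow(morph, prop_orange, prop_yellow),
    }

    def homozygous(trait: str) -> bool:
        return eff[trait] > assumption.ref_mean(trait, sex)

    if model.name == "model2":
        # ambiguous only for O (OO vs OG) and Y (YY vs YG)
        trait = "orange" if morph == "O" else "yellow"
        symbol = "O" if morph == "O" else "Y"
        pair = (symbol, symbol) if homozygous(trait) else tuple(sorted((symbol, "G")))
        return {((pair),): 1.0}
    if model.name == "model3":
        orange_pair = (
            ("O", "O") if homozygous("orange") else ("O", "o")
        )
        yellow_pair = (
            ("Y", "Y") if homozygous("yellow") else ("Y", "y")
        )
        locus_states = []
        for locus in model.loci:
            if locus.name == "orange":
                locus_states.append(
                    tuple(sorted(orange_pair)) if morph in ("O", "OY") else ("o", "o")
                )
            else:
                locus_states.append(
                    tuple(sorted(yellow_pair)) if morph in ("Y", "OY") else ("y", "y")
                )
        return {tuple(locus_states): 1.0}
    raise ValueError(
        f"threshold scheme is not defined for {model.name} (ambiguous dominance)"
    )


# ---------------------------------------------------------------------------
# Allele-frequency estimation from adult phenotype counts


def estimate_allele_frequencies(
    adult_counts: MorphCounts, model: GeneticModel
) -> Dict[str, Dict[str, float]]:
    """Moment estimates of allele frequencies from adult morph fractions.

    model3: the absence classes are double-recessive, so
    freq(y) = sqrt(f_G + f_O) and freq(o) = sqrt(f_G + f_Y).
    model2: g = sqrt(f_G), o = sqrt(f_O + g^2) - g, y = sqrt(f_Y + g^2) - g,
    renormalized to sum to one.
    """
    total = adult_counts.total
    if total <= 0:
        raise ValueError("adult_counts total must be positive")
    f = {m: getattr(adult_counts, m) / total for m in MORPHS}

    if model.name == "model3":
        freq_y = math.sqrt(f["G"] + f["O"])
        freq_o = math.sqrt(f["G"] + f["Y"])
        return {
            "orange": {"O": 1.0 - freq_o, "o": freq_o},
            "yellow": {"Y": 1.0 - freq_y, "y": freq_y},
        }
    if model.name == "model2":
        if f["G"] <= 0:
            raise ValueError(
                "model2 allele frequencies are unidentifiable when no grey "
                "morphs are observed; use the equal or threshold scheme"
            )
        g = math.sqrt(f["G"])
        o = math.sqrt(f["O"] + g * g) - g
        y = math.sqrt(f["Y"] + g * g) - g
        norm = o + y + g
        return {"colour": {"O": o / norm, "Y": y / norm, "G": g / norm}}
    raise ValueError(f"allele-frequency estimation undefined for {model.name}")


# ---------------------------------------------------------------------------
# Crossing


def _gametes(genotype: Genotype) -> List[Tuple[Tuple[str, ...], float]]:
    """Enumerate gametes (one allele per locus) with probabilities."""
    per_locus: List[List[Tuple[str, float]]] = []
    for pair in genotype:
        if len(pair) == 1:
            per_locus.append([(pair[0], 1.0)])
        elif pair[0] == pair[1]:
            per_locus.append([(pair[0], 1.0)])
        else:
            per_locus.append([(pair[0], 0.5), (pair[1], 0.5)])
    out: List[Tuple[Tuple[str, ...], float]] = []
    for combo in product(*per_locus):
        alleles = tuple(a for a, _ in combo)
        prob = 1.0
        for _, p in combo:
            prob *= p
        out.append((alleles, prob))
    return out


def cross(
    sire_dist: GenotypeDistribution,
    dam_dist: GenotypeDistribution,
    model: GeneticModel,
) -> Dict[str, Dict[str, float]]:
    """Expected offspring morph probabilities per offspring sex.

    Returns ``{"male": {...}, "female": {...}, "unknown": {...}}`` where
    ``unknown`` is the unweighted son/daughter average. Under Z linkage,
    sons combine one paternal and the maternal Z allele per locus; daughters
    are hemizygous for a paternal gamete.
    """
    if model.linkage == "z_linked":
        for g in dam_dist:
            if any(len(pair) != 1 for pair in g):
                raise ValueError("z_linked dam genotypes must be hemizygous")
        for g in sire_dist:
            if any(len(pair) != 2 for pair in g):
                raise ValueError("z_linked sire genotypes must be diploid")

    son = {m: 0.0 for m in MORPHS}
    daughter = {m: 0.0 for m in MORPHS}
    for gs, ps in sire_dist.items():
        sire_gametes = _gametes(gs)
        for gd, pd in dam_dist.items():
            w_pair = ps * pd
            if model.linkage == "autosomal":
                dam_gametes = _gametes(gd)
                for sg, wsg in sire_gametes:
                    for dg, wdg in dam_gametes:
                        child = tuple(
                            tuple(sorted((a, b))) for a, b in zip(sg, dg)
                        )
                        morph = phenotype_of(child, model)
                        son[morph] += w_pair * wsg * wdg
                daughter = son  # identical; fixed up below
            else:
                maternal_z = tuple(pair[0] for pair in gd)
                for sg, wsg in sire_gametes:
                    boy = tuple(
                        tuple(sorted((a, b))) for a, b in zip(sg, maternal_z)
                    )
                    son[phenotype_of(boy, model)] += w_pair * wsg
                    girl = tuple((a,) for a in sg)
                    daughter[phenotype_of(girl, model)] += w_pair * wsg
    if model.linkage == "autosomal":
        daughter = dict(son)
    for vec in (son, daughter):
        total = sum(vec.values())
        if abs(total - 1.0) > 1e-9:
            raise AssertionError(f"cross probabilities sum to {total}")
    unknown = {m: 0.5 * (son[m] + daughter[m]) for m in MORPHS}
    return {"male": son, "female": daughter, "unknown": unknown}


# ---------------------------------------------------------------------------
# Expected offspring frequencies over a pedigree and the G test


def _dist_key(dist: GenotypeDistribution) -> Tuple:
    return tuple(sorted((g, round(p, 15)) for g, p in dist.items()))


def expected_offspring_frequencies(
    pedigree: Pedigree,
    model: GeneticModel,
    assumption: ZygosityAssumption,
) -> Tuple[MorphCounts, MorphCounts, int]:
    """Expected vs observed morph counts over all phenotyped offspring.

    Each offspring contributes its mating's morph probability vector (own
    sex's vector under Z linkage; son/daughter average when unsexed).
    Offspring with an unknown own or parental morph are skipped from both
    tallies. Returns (expected, observed, n_skipped).
    """
    expected = {m: 0.0 for m in MORPHS}
    observed = {m: 0 for m in MORPHS}
    skipped = 0
    cross_cache: Dict[Tuple, Dict[str, Dict[str, float]]] = {}

    def parent_dist(parent: Individual) -> GenotypeDistribution:
        return parental_genotype_distribution(
            parent.morph,
            parent.sex,
            model,
            assumption,
            prop_orange=parent.prop_orange,
            prop_yellow=parent.prop_yellow,
        )

    for ind in pedigree:
        if ind.is_founder or ind.morph is None:
            continue
        if ind.sire_id is None or ind.dam_id is None:
            skipped += 1
            continue
        sire = pedigree[ind.sire_id]
        dam = pedigree[ind.dam_id]
        if sire.morph is None or dam.morph is None:
            logger.warning(
                "offspring %s skipped: parent morph unknown", ind.id
            )
            skipped += 1
            continue
        sire_dist = parent_dist(sire)
        dam_dist = parent_dist(dam)
        key = (_dist_key(sire_dist), _dist_key(dam_dist))
        if key not in cross_cache:
            cross_cache[key] = cross(sire_dist, dam_dist, model)
        vectors = cross_cache[key]
        sex = ind.sex if ind.sex in ("male", "female") else "unknown"
        vec = vectors[sex]
        for m in MORPHS:
            expected[m] += vec[m]
        observed[ind.morph] += 1

    return (
        MorphCounts.from_mapping(expected),
        MorphCounts.from_mapping(observed),
        skipped,
    )


@dataclass(frozen=True)
class GTestResult:
    G: float
    df: int
    p: float
    infinite: bool = False


def g_test(observed: MorphCounts, expected: MorphCounts, df: int = 3) -> GTestResult:
    """Likelihood-ratio goodness of fit: G = 2 * sum O_i ln(O_i / E_i).

    Categories with O_i = 0 contribute nothing; E_i = 0 with O_i > 0 yields
    an infinite G flagged as an incompatibility rather than an exception.
    """
    g = 0.0
    infinite = False
    for m in MORPHS:
        o = getattr(observed, m)
        e = getattr(expected, m)
        if o == 0:
            continue
        if e <= 0:
            infinite = True
            continue
        g += o * math.log(o / e)
    if infinite:
        return GTestResult(math.inf, df, 0.0, infinite=True)
    g *= 2.0
    if g < 0 and g > -1e-12:
        g = 0.0
    return GTestResult(g, df, float(stats.chi2.sf(g, df)))


@dataclass
class ModelFitResult:
    model: str
    scheme: str
    expected: Optional[MorphCounts]
    observed: Optional[MorphCounts]
    G: Optional[float]
    df: Optional[int]
    p: Optional[float]
    error: Optional[str] = None
    best: bool = False

    @property
    def evaluable(self) -> bool:
        return self.error is None


def reference_expression_means(
    pedigree: Pedigree,
    thresholds: ExpressionThresholds = ExpressionThresholds(),
) -> Dict[str, Dict[str, float]]:
    """Sex-specific mean effective colour proportions over F0 adults.

    Below-threshold values count as zero expression, so the means are taken
    over the whole adult reference group (zeros included), matching how the
    population mean proportion is defined for the threshold scheme."""
    sums: Dict[Tuple[str, str], List[float]] = {}
    for ind in pedigree:
        from .pedigree import _generation_number

        if _generation_number(ind.generation) not in (0, None):
            continue
        if ind.prop_orange is None or ind.prop_yellow is None or ind.morph is None:
            continue
        if ind.sex not in ("male", "female"):
            continue
        orange = (
            ind.prop_orange
            if is_expressed(ind.prop_orange, "orange", "adult", thresholds)
            else 0.0
        )
        yellow = (
            effective_yellow(ind.morph, ind.prop_orange, ind.prop_yellow)
            if is_expressed(ind.prop_yellow, "yellow", "adult", thresholds)
            else 0.0
        )
        sums.setdefault(("orange", ind.sex), []).append(orange)
        sums.setdefault(("yellow", ind.sex), []).append(yellow)
    means: Dict[str, Dict[str, float]] = {}
    for trait in ("orange", "yellow"):
        per_sex = {}
        for sex in ("male", "female"):
            values = sums.get((trait, sex))
            if values:
                per_sex[sex] = float(np.mean(values))
        if not per_sex:
            raise ValueError(
                f"no measured F0 adults to compute a reference mean for {trait}"
            )
        # fall back to the other sex's mean if one sex has no expressers
        for sex in ("male", "female"):
            per_sex.setdefault(sex, next(iter(per_sex.values())))
        means[trait] = per_sex
    return means


def fit_all_models(
    pedigree: Pedigree,
    schemes: Sequence[str] = ("equal", "hwe", "threshold"),
    models: Sequence[str] = ("model2", "model3"),
    thresholds: ExpressionThresholds = ExpressionThresholds(),
    df: int = 3,
    reference_means: Optional[Mapping] = None,
) -> List[ModelFitResult]:
    """Fit each autosomal model x zygosity scheme; flag the best (largest p).

    HWE allele frequencies are estimated from F0 adult males (all F0 adults
    when no males carry a morph); threshold reference means likewise come
    from F0 adults unless supplied.
    """
    from .pedigree import _generation_number, morph_counts

    def is_adult_male(ind: Individual) -> bool:
        return (
            _generation_number(ind.generation) == 0
            and ind.sex == "male"
            and ind.morph is not None
        )

    def is_adult(ind: Individual) -> bool:
        return _generation_number(ind.generation) == 0 and ind.morph is not None

    adult_counts = morph_counts(pedigree, is_adult_male)
    if adult_counts.total == 0:
        adult_counts = morph_counts(pedigree, is_adult)

    results: List[ModelFitResult] = []
    for model_name in models:
        model = get_model(model_name, "autosomal")
        for scheme in schemes:
            try:
                if scheme == "hwe":
                    assumption = ZygosityAssumption(
                        "hwe",
                        allele_freqs=estimate_allele_frequencies(adult_counts, model),
                    )
                elif scheme == "threshold":
                    means = reference_means or reference_expression_means(
                        pedigree, thresholds
                    )
                    assumption = ZygosityAssumption(
                        "threshold", reference_means=means
                    )
                else:
                    assumption = ZygosityAssumption("equal")
                expected, observed, _ = expected_offspring_frequencies(
                    pedigree, model, assumption
                )
                gres = g_test(observed, expected, df=df)
                results.append(
                    ModelFitResult(
                        model_name,
                        scheme,
                        expected,
                        observed,
                        gres.G,
                        gres.df,
                        gres.p,
                    )
                )
            except ValueError as exc:
                results.append(
                    ModelFitResult(
                        model_name, scheme, None, None, None, None, None, str(exc)
                    )
                )
    evaluable = [r for r in results if r.evaluable and math.isfinite(r.G)]
    if evaluable:
        best = max(evaluable, key=lambda r: r.p)
        best.best = True
    results.sort(key=lambda r: (r.p is None, -(r.p or 0.0)))
    return results


# ---------------------------------------------------------------------------
# Categorical exclusion checks


@dataclass(frozen=True)
class ExclusionReport:
    model: str
    linkage: str
    n_checked: int
    n_incompatible: int
    offending_ids: Tuple[str, ...]
    rule_counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def fraction_incompatible(self) -> float:
        return self.n_incompatible / self.n_checked if self.n_checked else 0.0


def model1_exclusion(pedigree: Pedigree, linkage: str = "autosomal") -> ExclusionReport:
    """One-locus four-allele necessary conditions.

    Autosomal: an offspring must share its morph with at least one parent.
    Z-linked: a daughter receives her single Z from her father, so she must
    express her father's morph.
    """
    checked = 0
    offenders: List[str] = []
    for ind in pedigree:
        if ind.is_founder or ind.morph is None:
            continue
        if ind.sire_id is None or ind.dam_id is None:
            continue
        sire = pedigree[ind.sire_id]
        dam = pedigree[ind.dam_id]
        if linkage == "autosomal":
            if sire.morph is None or dam.morph is None:
                continue
            checked += 1
            if ind.morph not in (sire.morph, dam.morph):
                offenders.append(ind.id)
        else:
            if ind.sex != "female" or sire.morph is None:
                continue
            checked += 1
            if ind.morph != sire.morph:
                offenders.append(ind.id)
    return ExclusionReport(
        "model1", linkage, checked, len(offenders), tuple(offenders)
    )


def zlinked_exclusion(pedigree: Pedigree, model: GeneticModel) -> ExclusionReport:
    """Z-linkage incompatibilities over father-daughter pairs.

    model3: a grey father cannot have non-grey daughters; a yellow father
    cannot have daughters expressing orange; an orange father cannot have
    daughters expressing yellow. model2: OY daughters are impossible
    outright (a hemizygous female carries a single co-dominant allele).
    """
    rules: Dict[str, int] = {}
    offenders: List[str] = []
    checked = 0
    for ind in pedigree:
        if ind.sex != "female" or ind.morph is None or ind.sire_id is None:
            continue
        sire = pedigree[ind.sire_id]
        if model.name == "model2":
            checked += 1
            if ind.morph == "OY":
                rules["oy_daughter"] = rules.get("oy_daughter", 0) + 1
                offenders.append(ind.id)
            continue
        if model.name == "model3":
            if sire.morph is None:
                continue
            checked += 1
            bad = False
            if sire.morph == "G" and ind.morph != "G":
                rules["grey_father_nongrey_daughter"] = (
                    rules.get("grey_father_nongrey_daughter", 0) + 1
                )
                bad = True
            if sire.morph == "Y" and ind.morph in ("O", "OY"):
                rules["yellow_father_orange_daughter"] = (
                    rules.get("yellow_father_orange_daughter", 0) + 1
                )
                bad = True
            if sire.morph == "O" and ind.morph in ("Y", "OY"):
                rules["orange_father_yellow_daughter"] = (
                    rules.get("orange_father_yellow_daughter", 0) + 1
                )
                bad = True
            if bad:
                offenders.append(ind.id)
            continue
        raise ValueError(f"zlinked_exclusion undefined for {model.name}")
    return ExclusionReport(
        model.name, "z_linked", checked, len(offenders), tuple(offenders), rules
    )
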
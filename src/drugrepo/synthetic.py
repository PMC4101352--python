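"""Seed-reproducible synthetic repositioning studies with recorded ground truth.

A study consists of: a gene universe; three partially overlapping drug–target
sources written in the three supported dialects; per-phenotype candidate sets
with nested significance tiers and six search spaces; planted
phenotype-matching indications for a controlled subset of targets (the
"known" targets); and per-gene citation counts drawn from an overdispersed
negative-binomial model with enriched means on true disease genes.

Every quantity the pipeline later reports (Venn region counts, TT, TI, RTT,
NTT, NV, confusion cells) is recorded in :class:`SyntheticTruth` at build
time from the planted sets, so recovery can be asserted exactly.  All
randomness flows from one ``numpy`` generator; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import indication_matches, load_synonyms

SOURCES = ("drugbank", "pharmgkb", "ttd")
SOURCE_DIALECTS = {"drugbank": "drugbank_like", "pharmgkb": "pharmgkb_like", "ttd": "ttd_like"}

#: Venn regions keyed by the sorted sources sharing the targets.
DEFAULT_VENN_FRACTIONS: dict[str, float] = {
    "drugbank": 0.60,
    "pharmgkb": 0.13,
    "ttd": 0.05,
    "drugbank|pharmgkb": 0.07,
    "drugbank|ttd": 0.09,
    "pharmgkb|ttd": 0.02,
    "drugbank|pharmgkb|ttd": 0.04,
}

_STATUS_VOCAB = (
    ("Approved", 0.35),
    ("Launched", 0.05),
    ("Phase I", 0.10),
    ("Phase II", 0.10),
    ("Phase III", 0.10),
    ("Preclinical", 0.10),
    ("Discontinued in phase II", 0.05),
    ("", 0.15),
)

_ACTION_VOCAB = ("inhibitor", "agonist", "antagonist", "activator", "modulator", "unknown")

#: Decoy indications; none may match any phenotype synonym (asserted at build).
DECOY_INDICATIONS = (
    "peptic ulcer disease",
    "kaposi's sarcoma",
    "advanced renal cell carcinoma",
    "cushing's syndrome",
    "psoriasis",
    "multiple sclerosis",
    "oral mucositis",
    "irritable bowel syndrome",
    "schizophrenia",
    "hyperlipidemia",
    "asthma",
    "migraine",
    "epilepsy",
    "osteoporosis",
    "glaucoma",
    "chronic obstructive pulmonary disease",
    "parkinson's disease",
    "alzheimer's disease",
    "breast cancer",
    "prostate cancer",
    "iron-deficiency anemia",
    "gout",
    "malaria",
    "tuberculosis",
    "hepatitis c",
    "influenza",
    "atopic dermatitis",
    "insomnia",
    "obesity",
    "osteoarthritis",
)


@dataclass(frozen=True)
class PhenotypePlan:
    """Study-design parameters for one phenotype."""

    code: str
    n_candidates: int
    targetable_fraction: float
    known_indication_rate: float  # among targetable candidates
    n_known_missed: int = 0  # known targets in the spaces but never predicted

    @property
    def n_targetable(self) -> int:
        return int(round(self.targetable_fraction * self.n_candidates))

    @property
    def n_known(self) -> int:
        return int(round(self.known_indication_rate * self.n_targetable))


#: Seven-phenotype demo mirroring the repositioning-potential geometry of the
#: WTCCC complex-disease study (candidate counts, targetable fractions,
#: replicated-target rates and missed known targets per phenotype).
DEFAULT_PHENOTYPES: tuple[PhenotypePlan, ...] = (
    PhenotypePlan("T2D", 291, 84 / 291, 7 / 84, 9),
    PhenotypePlan("T1D", 358, 97 / 358, 2 / 97, 9),
    PhenotypePlan("RA", 200, 77 / 200, 6 / 77, 9),
    PhenotypePlan("HT", 219, 78 / 219, 5 / 78, 15),
    PhenotypePlan("BD", 212, 59 / 212, 1 / 59, 6),
    PhenotypePlan("CD", 378, 135 / 378, 0.0, 0),
    PhenotypePlan("CAD", 264, 102 / 264, 4 / 102, 8),
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults define the demo conditions."""

    genome_size: int = 20000
    n_targets: int = 1600  # union of human targets across the three sources
    venn_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VENN_FRACTIONS)
    )
    drugs_per_target_mean: float = 2.5  # multiplicity = 1 + Poisson(mean - 1)
    drug_pool_size: int | None = None  # None -> derived from n_targets
    fresh_drug_per_association: bool = False  # True: every association its own drug
    nonhuman_fraction: float = 0.2  # extra nonhuman rows, relative to human rows
    uniprot_alias_fraction: float = 0.3  # ttd rows using accession tokens
    phenotypes: tuple[PhenotypePlan, ...] = DEFAULT_PHENOTYPES
    tier_fractions: dict[str, float] = field(
        default_factory=lambda: {"HS": 0.1, "MHS": 0.3, "MWS": 0.6, "WS": 1.0}
    )
    space_multipliers: tuple[float, ...] = (2, 3, 4, 6, 9, 14)
    pred_fractions: tuple[float, ...] = (0.35, 0.5, 0.65, 0.8, 0.9, 1.0)
    citation_baseline_mean: float = 2.0
    citation_dispersion: float = 2.0
    citation_enrichment: float = 5.0
    true_fraction_predicted: float = 0.4  # true disease genes among candidates
    true_fraction_background: float = 0.02  # ... among non-candidate space genes
    #: fraction of non-known true candidate genes drawn from the targetable
    #: subset — the knowledge bias: well-characterized disease genes tend to be
    #: both heavily cited and druggable
    true_targetable_bias: float = 0.8
    #: <1 concentrates known targets near the top of the prediction ranking
    #: (they fall uniformly within the top ``known_rank_bias`` fraction);
    #: 1.0 leaves the ranking uninformative
    known_rank_bias: float = 1.0

    def validate(self) -> None:
        if self.genome_size < 100:
            raise ValueError("genome_size must be at least 100")
        total = sum(self.venn_fractions.values())
        if not 0 < total <= 1.0 + 1e-9:
            raise ValueError("Venn region fractions must sum to a value in (0, 1]")
        if any(f < 0 for f in self.venn_fractions.values()):
            raise ValueError("Venn fractions must be non-negative")
        for plan in self.phenotypes:
            if not 0 <= plan.targetable_fraction <= 1:
                raise ValueError(f"{plan.code}: targetable_fraction outside [0, 1]")
            if not 0 <= plan.known_indication_rate <= 1:
                raise ValueError(f"{plan.code}: known_indication_rate outside [0, 1]")
        fr = [self.tier_fractions[t] for t in ("HS", "MHS", "MWS", "WS")]
        if not all(a < b for a, b in zip(fr, fr[1:])):
            raise ValueError("tier fractions must be strictly increasing HS < MHS < MWS < WS")
        if any(m < 1 for m in self.space_multipliers):
            raise ValueError("search-space multipliers must be >= 1")
        if len(self.space_multipliers) != len(self.pred_fractions):
            raise ValueError("space_multipliers and pred_fractions must align")
        if self.pred_fractions[-1] != 1.0:
            raise ValueError("the loosest search space must predict every candidate")


#: Scaled-down single-phenotype study with strongly enriched predictions, used
#: for the seeded significance-direction experiments.
ENRICHED_STUDY_CONFIG = GeneratorConfig(
    genome_size=4000,
    n_targets=800,
    phenotypes=(PhenotypePlan("T2D", 200, 0.30, 0.25, 5),),
    space_multipliers=(2, 3, 4, 5, 7, 10),
    pred_fractions=(0.3, 0.45, 0.6, 0.75, 0.9, 1.0),
    known_rank_bias=0.5,
)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTruth:
    code: str
    n_candidates: int
    candidates: list[str]
    targetable: list[str]  # == expected predicted targets (TT)
    known_predicted: list[str]  # expected replicated targets (RTT)
    known_missed: list[str]  # in search spaces, never predicted
    true_genes: list[str]  # citation-enriched genes
    expected_TT: int
    expected_RTT: int
    expected_NTT: int
    expected_TI: float
    expected_NV: float | None
    space_sizes: list[int]
    expected_confusion: list[dict]  # per search space: tp/fp/fn/tn


@dataclass
class SyntheticTruth:
    """Everything the pipeline should recover, recorded at generation time."""

    seed: int
    genome_size: int
    venn_regions: dict[str, int]  # planted human-target region counts
    union_targets: int
    per_source_targets: dict[str, int]
    per_source_drugs: dict[str, int]  # realized drug-name keys per source
    per_source_associations_human: dict[str, int]
    per_source_associations_nonhuman: dict[str, int]
    phenotypes: dict[str, PhenotypeTruth]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        payload["phenotypes"] = {
            k: PhenotypeTruth(**v) for k, v in payload["phenotypes"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_genome(config: GeneratorConfig) -> list[str]:
    """Deterministic gene universe G00001..G<genome_size>."""
    if config.genome_size < 100:
        raise ValueError("genome_size must be at least 100")
    return [f"G{i:05d}" for i in range(1, config.genome_size + 1)]


def _apportion(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over labelled fractions."""
    keys = sorted(fractions)
    quotas = {k: n * fractions[k] for k in keys}
    counts = {k: int(quotas[k]) for k in keys}
    short = n - sum(counts.values()) if sum(fractions.values()) > 1 - 1e-9 else 0
    if short > 0:
        by_rem = sorted(keys, key=lambda k: (-(quotas[k] - counts[k]), k))
        for k in by_rem[:short]:
            counts[k] += 1
    if all(c == 0 for c in counts.values()):
        raise ValueError("infeasible Venn region sizes: every region rounded to zero")
    return counts


@dataclass
class SourceTables:
    """Raw dialect rows per source plus generation-side bookkeeping."""

    rows: dict[str, list[dict]]
    alias_rows: list[dict]
    target_sets: dict[str, set[str]]  # human targets per source
    drug_keys: dict[str, set[str]]
    n_human_assoc: dict[str, int]
    n_nonhuman_assoc: dict[str, int]
    gene_sources: dict[str, list[str]]  # gene -> sources carrying it


def generate_drug_sources(
    config: GeneratorConfig, genome: Sequence[str], rng: np.random.Generator
) -> tuple[SourceTables, dict[str, int]]:
    """Plant targets into Venn regions and attach drugs, statuses, indications.

    Returns the raw per-source dialect rows plus the planted region counts.
    """
    config.validate()
    region_counts = _apportion(config.n_targets, config.venn_fractions)
    n_planted = sum(region_counts.values())
    pool = list(rng.choice(np.array(genome), size=n_planted, replace=False))

    target_sets: dict[str, set[str]] = {s: set() for s in SOURCES}
    gene_sources: dict[str, list[str]] = {}
    idx = 0
    for region in sorted(region_counts):
        members = region.split("|")
        for g in pool[idx : idx + region_counts[region]]:
            for s in members:
                target_sets[s].add(g)
            gene_sources[g] = members
        idx += region_counts[region]

    n_pool = config.drug_pool_size or max(30, int(n_planted * config.drugs_per_target_mean * 0.6))
    drug_names = [f"Drug{i:05d}" for i in range(1, n_pool + 1)]
    status_texts = [s for s, _ in _STATUS_VOCAB]
    status_probs = np.array([p for _, p in _STATUS_VOCAB])
    drug_status = {
        d: status_texts[i]
        for d, i in zip(drug_names, rng.choice(len(status_texts), size=n_pool, p=status_probs))
    }
    drug_indication = {
        d: DECOY_INDICATIONS[i]
        for d, i in zip(drug_names, rng.integers(0, len(DECOY_INDICATIONS), size=n_pool))
    }

    accession = {g: f"P{10000 + i}" for i, g in enumerate(pool)}
    alias_rows = [
        {"input_token": accession[g], "canonical_symbol": g} for g in sorted(accession)
    ]

    rows: dict[str, list[dict]] = {s: [] for s in SOURCES}
    drug_keys: dict[str, set[str]] = {s: set() for s in SOURCES}
    n_human = {s: 0 for s in SOURCES}
    fresh_counter = 0

    pharmgkb_genes: dict[str, list[str]] = {}  # drug -> genes (one row per drug)

    for source in SOURCES:
        for gene in sorted(target_sets[source]):
            k = 1 + (rng.poisson(config.drugs_per_target_mean - 1.0) if config.drugs_per_target_mean > 1 else 0)
            if config.fresh_drug_per_association:
                drawn = []
                for _ in range(k):
                    fresh_counter += 1
                    name = f"Fresh{fresh_counter:06d}"
                    drug_status[name] = status_texts[int(rng.choice(len(status_texts), p=status_probs))]
                    drug_indication[name] = DECOY_INDICATIONS[int(rng.integers(0, len(DECOY_INDICATIONS)))]
                    drawn.append(name)
            else:
                drawn = [drug_names[i] for i in rng.choice(n_pool, size=min(k, n_pool), replace=False)]
            for d in drawn:
                n_human[source] += 1
                drug_keys[source].add(d.lower())
                action = _ACTION_VOCAB[int(rng.integers(0, len(_ACTION_VOCAB)))]
                if source == "drugbank":
                    rows["drugbank"].append(
                        {
                            "drug_id": f"DB{zlib.crc32(d.encode()) % 10**5:05d}",
                            "drug_name": d,
                            "brand_names": f"{d} XR" if rng.random() < 0.2 else "",
                            "gene_symbol": gene,
                            "species": "Human",
                            "action": action,
                            "indication": drug_indication[d],
                            "status": drug_status[d],
                        }
                    )
                elif source == "pharmgkb":
                    pharmgkb_genes.setdefault(d, []).append(gene)
                else:
                    use_acc = rng.random() < config.uniprot_alias_fraction
                    rows["ttd"].append(
                        {
                            "drug_name": d,
                            "target_uniprot_or_symbol": accession[gene] if use_acc else gene,
                            "disease": drug_indication[d],
                            "status": drug_status[d],
                            "action": action,
                        }
                    )

    for d in sorted(pharmgkb_genes):
        rows["pharmgkb"].append(
            {
                "drug_name": d,
                "associated_genes": "|".join(sorted(pharmgkb_genes[d])),
                "description": f"Used in management of {drug_indication[d]}.",
            }
        )

    # nonhuman rows exercise the species filter; symbols live outside the genome
    n_nonhuman = {s: 0 for s in SOURCES}
    n_nh = int(round(config.nonhuman_fraction * n_human["drugbank"]))
    for i in range(n_nh):
        if config.fresh_drug_per_association:
            d = f"FreshNH{i:06d}"
            drug_status[d] = "Approved"
        else:
            d = drug_names[int(rng.integers(0, n_pool))]
        rows["drugbank"].append(
            {
                "drug_id": f"DB9{i:04d}",
                "drug_name": d,
                "brand_names": "",
                "gene_symbol": f"NHGENE{i:05d}",
                "species": "Bacterial" if i % 2 == 0 else "Fungal",
                "action": "inhibitor",
                "indication": DECOY_INDICATIONS[i % len(DECOY_INDICATIONS)],
                "status": drug_status[d],
            }
        )
        n_nonhuman["drugbank"] += 1

    tables = SourceTables(
        rows=rows,
        alias_rows=alias_rows,
        target_sets=target_sets,
        drug_keys=drug_keys,
        n_human_assoc=n_human,
        n_nonhuman_assoc=n_nonhuman,
        gene_sources=gene_sources,
    )
    return tables, region_counts


def _plant_indicated_drug(
    tables: SourceTables,
    gene: str,
    phenotype: str,
    indication: str,
    status_text: str,
) -> None:
    """Attach a dedicated phenotype-indicated drug to a gene.

    The row goes into a source that already carries the gene so that planted
    Venn region counts are untouched.
    """
    source = sorted(tables.gene_sources[gene])[0]
    name = f"{phenotype}-{gene}-therapy"
    tables.drug_keys[source].add(name.lower())
    tables.n_human_assoc[source] += 1
    if source == "drugbank":
        tables.rows["drugbank"].append(
            {
                "drug_id": f"DBP{zlib.crc32(name.encode()) % 10**4:04d}",
                "drug_name": name,
                "brand_names": "",
                "gene_symbol": gene,
                "species": "Human",
                "action": "agonist",
                "indication": indication,
                "status": status_text,
            }
        )
    elif source == "pharmgkb":
        tables.rows["pharmgkb"].append(
            {
                "drug_name": name,
                "associated_genes": gene,
                "description": f"Registered therapy for {indication}.",
            }
        )
    else:
        tables.rows["ttd"].append(
            {
                "drug_name": name,
                "target_uniprot_or_symbol": gene,
                "disease": indication,
                "status": status_text,
                "action": "agonist",
            }
        )


def generate_phenotype_study(
    config: GeneratorConfig,
    genome: Sequence[str],
    tables: SourceTables,
    region_counts: dict[str, int],
    rng: np.random.Generator,
    synonyms: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw candidates, tiers, search spaces, known indications and citations.

    Appends planted indication rows to the source tables (in place), and
    returns the candidates frame, the citations frame and the full truth.
    """
    config.validate()
    synonyms = synonyms or load_synonyms()
    all_syns = [s for ph in synonyms.values() for s in ph.synonyms]
    for decoy in DECOY_INDICATIONS:
        assert not indication_matches(decoy, all_syns), f"decoy '{decoy}' matches a synonym"

    union_targets = sorted(set().union(*tables.target_sets.values()))
    target_set = set(union_targets)
    non_targets = sorted(set(genome) - target_set)

    cand_rows: list[dict] = []
    cit_rows: list[dict] = []
    pheno_truth: dict[str, PhenotypeTruth] = {}

    for plan in sorted(config.phenotypes, key=lambda p: p.code):
        if plan.code not in synonyms:
            raise ValueError(f"no synonym entry for phenotype {plan.code}")
        plant_synonym = synonyms[plan.code].synonyms[0]
        others = [
            s for code, ph in synonyms.items() if code != plan.code for s in ph.synonyms
        ]
        assert not indication_matches(plant_synonym, others), (
            f"planted indication '{plant_synonym}' is ambiguous across phenotypes"
        )

        n_t = plan.n_targetable
        if n_t > len(union_targets):
            raise ValueError(
                f"{plan.code}: targetable_fraction demands {n_t} targetable genes, "
                f"only {len(union_targets)} exist"
            )
        targetable = list(rng.choice(np.array(union_targets), size=n_t, replace=False))
        non_t = list(
            rng.choice(np.array(non_targets), size=plan.n_candidates - n_t, replace=False)
        )
        known_predicted = sorted(
            rng.choice(np.array(sorted(targetable)), size=plan.n_known, replace=False)
        ) if plan.n_known else []

        # prediction ranking: uniform scores, optionally squeezed toward the
        # top for known targets (enriched-confidence designs)
        unordered = targetable + non_t
        scores = rng.random(len(unordered))
        known_set_tmp = set(known_predicted)
        for i, g in enumerate(unordered):
            if g in known_set_tmp:
                scores[i] *= config.known_rank_bias
        candidates = [unordered[i] for i in np.argsort(scores, kind="stable")]
        missed_pool = sorted(target_set - set(candidates))
        if plan.n_known_missed > len(missed_pool):
            raise ValueError(f"{plan.code}: not enough targets outside candidates for misses")
        known_missed = sorted(
            rng.choice(np.array(missed_pool), size=plan.n_known_missed, replace=False)
        ) if plan.n_known_missed else []

        for g in known_predicted + known_missed:
            status_text = "Approved" if rng.random() < 0.6 else "Phase II"
            _plant_indicated_drug(tables, g, plan.code, plant_synonym, status_text)

        # nested search spaces: background pool leads with the missed knowns
        bg_rest = sorted(set(genome) - set(candidates) - set(known_missed))
        bg_order = rng.permutation(len(bg_rest))
        bg_pool = list(known_missed) + [bg_rest[i] for i in bg_order]

        known_all = set(known_predicted) | set(known_missed)
        space_sizes: list[int] = []
        confusion: list[dict] = []
        for sid, (mult, pf) in enumerate(
            zip(config.space_multipliers, config.pred_fractions), start=1
        ):
            k = int(round(pf * plan.n_candidates))
            pred = candidates[:k]
            n_bg = int(round(mult * k)) - k
            if n_bg > len(bg_pool):
                raise ValueError(f"{plan.code}: search space {sid} larger than the genome")
            space = pred + bg_pool[:n_bg]
            space_sizes.append(len(space))
            for g in space:
                cand_rows.append(
                    {
                        "phenotype": plan.code,
                        "tier": "WS",
                        "search_space_id": sid,
                        "gene_symbol": g,
                        "in_predicted_set": str(g in set(pred)).lower(),
                    }
                )
            pred_set, space_set = set(pred), set(space)
            tp = len(pred_set & target_set & known_all)
            fp = len((pred_set & target_set) - known_all)
            fn = len((known_all & space_set) - pred_set)
            confusion.append(
                {"search_space_id": sid, "tp": tp, "fp": fp, "fn": fn, "tn": len(space) - tp - fp - fn}
            )

        # stricter tiers: nested prefixes of the candidate list (space id 0)
        for tier in ("HS", "MHS", "MWS"):
            cut = int(round(config.tier_fractions[tier] * plan.n_candidates))
            tier_set = set(candidates[:cut])
            for g in candidates:
                cand_rows.append(
                    {
                        "phenotype": plan.code,
                        "tier": tier,
                        "search_space_id": 0,
                        "gene_symbol": g,
                        "in_predicted_set": str(g in tier_set).lower(),
                    }
                )

        # true disease genes: knowns, plus draws from candidates and background,
        # with the targetable candidates over-represented (knowledge bias)
        n_true_pred = int(round(config.true_fraction_predicted * plan.n_candidates))
        n_extra = max(0, n_true_pred - len(known_predicted))
        pool_t = sorted(set(targetable) - set(known_predicted))
        pool_nt = sorted(set(candidates) - set(targetable))
        n_bias = min(int(round(config.true_targetable_bias * n_extra)), len(pool_t))
        n_rest = min(n_extra - n_bias, len(pool_nt))
        true_pred = set(known_predicted)
        if n_bias:
            true_pred |= set(rng.choice(np.array(pool_t), size=n_bias, replace=False))
        if n_rest:
            true_pred |= set(rng.choice(np.array(pool_nt), size=n_rest, replace=False))
        largest_space = candidates + bg_pool[: space_sizes[-1] - plan.n_candidates]
        bg_genes = sorted(set(largest_space) - set(candidates) - set(known_missed))
        n_true_bg = int(round(config.true_fraction_background * len(bg_genes)))
        true_bg = set(known_missed) | set(
            rng.choice(np.array(bg_genes), size=n_true_bg, replace=False)
        ) if bg_genes else set(known_missed)
        true_genes = sorted(true_pred | true_bg)

        # overdispersed citation counts, enriched on true genes
        m, disp, r = (
            config.citation_baseline_mean,
            config.citation_dispersion,
            config.citation_enrichment,
        )
        truth_set = set(true_genes)
        for g in sorted(set(largest_space)):
            mean = m * r if g in truth_set else m
            n_cit = int(rng.negative_binomial(disp, disp / (disp + mean)))
            cit_rows.append(
                {"gene_symbol": g, "phenotype_code": plan.code, "n_citations": n_cit}
            )

        tt = n_t
        rtt = len(known_predicted)
        pheno_truth[plan.code] = PhenotypeTruth(
            code=plan.code,
            n_candidates=plan.n_candidates,
            candidates=sorted(candidates),
            targetable=sorted(targetable),
            known_predicted=list(known_predicted),
            known_missed=list(known_missed),
            true_genes=true_genes,
            expected_TT=tt,
            expected_RTT=rtt,
            expected_NTT=tt - rtt,
            expected_TI=tt / plan.n_candidates,
            expected_NV=(tt - rtt) / tt if tt else None,
            space_sizes=space_sizes,
            expected_confusion=confusion,
        )

    truth = SyntheticTruth(
        seed=seed,
        genome_size=config.genome_size,
        venn_regions=dict(region_counts),
        union_targets=len(target_set),
        per_source_targets={s: len(tables.target_sets[s]) for s in SOURCES},
        per_source_drugs={s: len(tables.drug_keys[s]) for s in SOURCES},
        per_source_associations_human=dict(tables.n_human_assoc),
        per_source_associations_nonhuman=dict(tables.n_nonhuman_assoc),
        phenotypes=pheno_truth,
    )
    candidates_df = pd.DataFrame(
        cand_rows,
        columns=["phenotype", "tier", "search_space_id", "gene_symbol", "in_predicted_set"],
    )
    citations_df = pd.DataFrame(
        cit_rows, columns=["gene_symbol", "phenotype_code", "n_citations"]
    )
    return candidates_df, citations_df, truth


def generate_study(
    config: GeneratorConfig, seed: int, outdir: str | Path
) -> SyntheticTruth:
    """Generate a complete study on disk, plus a ready-to-run pipeline config.

    Layout: sources/{drugbank,pharmgkb,ttd}.tsv, aliases.tsv, candidates.tsv,
    citations.tsv, synonyms.json, truth.json, run.json.
    """
    outdir = Path(outdir)
    (outdir / "sources").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = generate_genome(config)
    tables, region_counts = generate_drug_sources(config, genome, rng)
    synonyms = load_synonyms()
    synonyms = {p.code: synonyms[p.code] for p in config.phenotypes}
    candidates_df, citations_df, truth = generate_phenotype_study(
        config, genome, tables, region_counts, rng, synonyms=synonyms, seed=seed
    )

    from .ingest import DIALECT_COLUMNS

    for source in SOURCES:
        df = pd.DataFrame(tables.rows[source], columns=DIALECT_COLUMNS[SOURCE_DIALECTS[source]])
        df.to_csv(outdir / "sources" / f"{source}.tsv", sep="\t", index=False)
    pd.DataFrame(tables.alias_rows, columns=["input_token", "canonical_symbol"]).to_csv(
        outdir / "aliases.tsv", sep="\t", index=False
    )
    candidates_df.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    citations_df.to_csv(outdir / "citations.tsv", sep="\t", index=False)
    (outdir / "synonyms.json").write_text(
        json.dumps({c: list(p.synonyms) for c, p in sorted(synonyms.items())}, indent=1)
    )
    truth.to_json(outdir / "truth.json")

    run_cfg = {
        "sources": [
            {"path": str(outdir / "sources" / f"{s}.tsv"), "dialect": SOURCE_DIALECTS[s], "id": s}
            for s in SOURCES
        ],
        "aliases": str(outdir / "aliases.tsv"),
        "candidates": str(outdir / "candidates.tsv"),
        "citations": str(outdir / "citations.tsv"),
        "synonyms": str(outdir / "synonyms.json"),
        "genome_size": config.genome_size,
        "citation_thresholds": [1, 5, 10, 15],
        "output_dir": str(outdir / "reports"),
        "seed": seed,
    }
    (outdir / "run.json").write_text(json.dumps(run_cfg, indent=1))
    return truth


# ---------------------------------------------------------------------------
# recovery verification
# ---------------------------------------------------------------------------


@dataclass
class RecoveryCheck:
    name: str
    expected: object
    actual: object

    @property
    def ok(self) -> bool:
        return self.expected == self.actual


@dataclass
class RecoveryReport:
    checks: list[RecoveryCheck]

    @property
    def passed(self) -> bool:
        return all(c.ok for c in self.checks)

    @property
    def failures(self) -> list[RecoveryCheck]:
        return [c for c in self.checks if not c.ok]

    def summary(self) -> str:
        lines = [f"truth recovery: {sum(c.ok for c in self.checks)}/{len(self.checks)} checks pass"]
        for c in self.failures:
            lines.append(f"  MISMATCH {c.name}: expected {c.expected!r}, got {c.actual!r}")
        return "\n".join(lines)


def verify_truth_recovery(bundle, truth: SyntheticTruth) -> RecoveryReport:
    """Assert every planted statistic against a pipeline report bundle.

    Set counts are compared exactly; ``bundle`` is the object returned by
    :func:`drugrepo.pipeline.run_pipeline`.
    """
    checks: list[RecoveryCheck] = []
    ov = bundle.overlap
    checks.append(RecoveryCheck("union_targets", truth.union_targets, ov.targets.union))
    for s, n in sorted(truth.per_source_targets.items()):
        checks.append(RecoveryCheck(f"targets[{s}]", n, ov.targets.per_source.get(s)))
    # region counts: recompute expected exclusive regions from planted counts
    region = truth.venn_regions
    triple = region.get("drugbank|pharmgkb|ttd", 0)
    checks.append(RecoveryCheck("triple_shared", triple, ov.targets.triple_shared))
    for a, b in (("drugbank", "pharmgkb"), ("drugbank", "ttd"), ("pharmgkb", "ttd")):
        planted = region.get(f"{a}|{b}", 0) + triple
        checks.append(
            RecoveryCheck(f"pairwise[{a}|{b}]", planted, ov.targets.pairwise_shared.get((a, b)))
        )
    for s in sorted(truth.per_source_targets):
        only = region.get(s, 0)
        checks.append(RecoveryCheck(f"unique[{s}]", only, ov.targets.unique_per_source.get(s)))
    for s, n in sorted(truth.per_source_drugs.items()):
        checks.append(RecoveryCheck(f"drugs[{s}]", n, ov.drugs.per_source.get(s)))
    for code, pt in sorted(truth.phenotypes.items()):
        rep = bundle.reports_by_phenotype.get(code)
        if rep is None:
            checks.append(RecoveryCheck(f"{code}: report present", True, False))
            continue
        checks.append(RecoveryCheck(f"{code}: TT", pt.expected_TT, rep.TT))
        checks.append(RecoveryCheck(f"{code}: RTT", pt.expected_RTT, rep.RTT))
        checks.append(RecoveryCheck(f"{code}: NTT", pt.expected_NTT, rep.NTT))
        checks.append(
            RecoveryCheck(f"{code}: replicated set", set(pt.known_predicted), set(rep.replicated_targets))
        )
        checks.append(
            RecoveryCheck(f"{code}: target set", set(pt.targetable), set(rep.replicated_targets) | set(rep.novel_targets))
        )
        if rep.TI is not None:
            checks.append(
                RecoveryCheck(f"{code}: TI", round(pt.expected_TI, 12), round(rep.TI.raw, 12))
            )
        if pt.expected_NV is not None and rep.NV is not None:
            checks.append(
                RecoveryCheck(f"{code}: NV", round(pt.expected_NV, 12), round(rep.NV.raw, 12))
            )
        cms = bundle.confusion_by_phenotype.get(code, [])
        for exp, cm in zip(pt.expected_confusion, cms):
            sid = exp["search_space_id"]
            checks.append(
                RecoveryCheck(
                    f"{code}: confusion space {sid}",
                    (exp["tp"], exp["fp"], exp["fn"], exp["tn"]),
                    (cm.tp, cm.fp, cm.fn, cm.tn),
                )
            )
    return RecoveryReport(checks=checks)
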
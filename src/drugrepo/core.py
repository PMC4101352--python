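"""Candidate-gene to drug-target mapping and repositioning statistics.

Per phenotype, the pipeline intersects predicted candidate genes with the
unified drug-target table, splits the resulting targets into *replicated*
(some drug hitting the gene is already registered for the phenotype) and
*novel*, and summarizes:

- Targetability Index ``TI = TT / n_candidates`` — the fraction of a
  phenotype's predicted candidates that are druggable today;
- novelty ratio ``NV = NTT / TT`` — the fraction of those targets with no
  registered therapy for the phenotype, i.e. the repositioning headroom;
- development-status strata (approved / clinical targets and their novel
  subsets).

Indication→phenotype matching is declarative: a phenotype is a code plus a
synonym list, and an indication counts as "this phenotype" when any synonym
occurs in the indication text on whole-word boundaries, case-insensitively.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd

from .ingest import UnifiedDrugTable

logger = logging.getLogger(__name__)

TIERS = ("HS", "MHS", "MWS", "WS")  # strictest to loosest SNP significance


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class RatioValue(NamedTuple):
    """A reported ratio: full precision plus the 2-dp half-up display form."""

    raw: float
    rounded: float


def _ratio(num: int, den: int) -> RatioValue:
    raw = num / den
    rounded = float((Decimal(num) / Decimal(den)).quantize(Decimal("0.01"), ROUND_HALF_UP))
    return RatioValue(raw, rounded)


# ---------------------------------------------------------------------------
# phenotypes and indication matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Phenotype:
    """A disease code with the indication strings that count as that disease."""

    code: str
    synonyms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("phenotype code must be non-empty")
        if not self.synonyms:
            raise ValueError(f"phenotype {self.code}: synonym list must be non-empty")


@lru_cache(maxsize=65536)
def _matches_cached(indication: str, synonyms: tuple[str, ...]) -> bool:
    text = indication.lower()
    for syn in synonyms:
        pat = r"(?<!\w)" + re.escape(syn.lower()) + r"(?!\w)"
        if re.search(pat, text):
            return True
    return False


def indication_matches(indication: str, synonyms: Iterable[str]) -> bool:
    """Whole-word, case-insensitive synonym match inside an indication string."""
    return _matches_cached(indication, tuple(synonyms))


def load_synonyms(path: str | Path | None = None) -> dict[str, Phenotype]:
    """Load a phenotype→synonym-list JSON config (default: the bundled one)."""
    if path is None:
        raw = resources.files("drugrepo.data").joinpath("phenotype_synonyms.json").read_text()
    else:
        raw = Path(path).read_text()
    data = json.loads(raw)
    return {code: Phenotype(code=code, synonyms=tuple(syns)) for code, syns in data.items()}


def load_known_therapeutics() -> pd.DataFrame:
    """Bundled reference table of replicated drug–target pairs.

    One row per (phenotype, target gene, registered drug) for the seven
    complex-disease phenotypes; the same gene may appear under more than one
    phenotype (e.g. AGTR1 for both hypertension and bipolar disorder), so
    the number of distinct genes is smaller than the row count.
    """
    with resources.as_file(
        resources.files("drugrepo.data").joinpath("known_therapeutics.tsv")
    ) as p:
        return pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)


def shared_synonyms(config: Mapping[str, Phenotype]) -> dict[str, list[str]]:
    """Report synonym strings listed under more than one phenotype.

    Sharing is legitimate (an unqualified 'diabetes mellitus' therapy counts
    for both diabetes phenotypes) but worth surfacing, so this is a check,
    not a validation error.
    """
    seen: dict[str, list[str]] = {}
    for code, ph in config.items():
        for syn in ph.synonyms:
            seen.setdefault(syn.lower(), []).append(code)
    return {syn: codes for syn, codes in seen.items() if len(codes) > 1}


# ---------------------------------------------------------------------------
# candidate gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateGeneSet:
    """Genes predicted for a phenotype at one significance tier × search space."""

    phenotype: str
    tier: str
    search_space_id: int
    genes: frozenset[str]
    search_space_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if not self.genes <= self.search_space_genes:
            extra = sorted(self.genes - self.search_space_genes)[:5]
            raise ValueError(
                f"{self.phenotype}/{self.tier}/space{self.search_space_id}: "
                f"predicted genes outside their search space, e.g. {extra}"
            )


def read_candidates(path: str | Path) -> list[CandidateGeneSet]:
    """Read the candidates TSV: [phenotype, tier, search_space_id, gene_symbol,
    in_predicted_set]; rows with in_predicted_set false define the background."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("phenotype", "tier", "search_space_id", "gene_symbol", "in_predicted_set")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column '{col}'")
    out: list[CandidateGeneSet] = []
    for (ph, tier, sid), grp in df.groupby(["phenotype", "tier", "search_space_id"], sort=True):
        flags = grp["in_predicted_set"].str.strip().str.lower().isin(("true", "1", "yes"))
        predicted = frozenset(grp.loc[flags, "gene_symbol"])
        space = frozenset(grp["gene_symbol"])
        out.append(
            CandidateGeneSet(
                phenotype=ph,
                tier=tier,
                search_space_id=int(sid),
                genes=predicted,
                search_space_genes=space,
            )
        )
    return out


def phenotype_candidate_union(sets: Sequence[CandidateGeneSet], phenotype: str) -> set[str]:
    """Phenotype-level candidate set: union over tiers and search spaces."""
    out: set[str] = set()
    for cs in sets:
        if cs.phenotype == phenotype:
            out |= cs.genes
    return out


# ---------------------------------------------------------------------------
# mapping and classification
# ---------------------------------------------------------------------------


def map_candidates_to_targets(
    candidates: Iterable[str] | CandidateGeneSet, unified: UnifiedDrugTable
) -> set[str]:
    """Intersect candidate genes with the unified target set."""
    genes = candidates.genes if isinstance(candidates, CandidateGeneSet) else set(candidates)
    if not genes:
        logger.warning("empty candidate set: mapping returns no targets")
        return set()
    return set(genes) & unified.targets


def targetability_index(n_targets: int, n_candidates: int) -> RatioValue:
    """TT / candidates; hard failure on an empty candidate set."""
    if n_candidates <= 0:
        raise ValueError("targetability index undefined for zero candidates")
    if n_targets > n_candidates:
        raise ValueError(f"n_targets {n_targets} > n_candidates {n_candidates}")
    return _ratio(n_targets, n_candidates)


def novelty_ratio(n_novel: int, n_targets: int) -> RatioValue:
    """NTT / TT; hard failure when no targets were predicted."""
    if n_targets <= 0:
        raise ValueError("novelty ratio undefined for zero predicted targets")
    if n_novel > n_targets:
        raise ValueError(f"n_novel {n_novel} > n_targets {n_targets}")
    return _ratio(n_novel, n_targets)


@dataclass(frozen=True)
class RepositioningCall:
    """One drug–gene–phenotype triple with its replicated/novel verdict."""

    drug_key: str
    gene: str
    phenotype: str
    current_indications: frozenset[str]
    status: str
    verdict: str  # 'replicated' or 'novel'


def indicated_drugs(phenotype: Phenotype, unified: UnifiedDrugTable) -> set[str]:
    """Drugs with at least one indication (pooled over sources/genes) matching
    the phenotype's synonyms."""
    return {
        d
        for d, inds in unified.drug_indications.items()
        if any(indication_matches(i, phenotype.synonyms) for i in inds)
    }


def replicated_target_set(phenotype: Phenotype, unified: UnifiedDrugTable) -> set[str]:
    """All unified targets whose own associations carry a matching indication.

    Gene-local on purpose: a drug registered for the phenotype via a
    different gene does not make this gene replicated (it only disqualifies
    the drug from the repositioning list, see
    :func:`enumerate_novel_drugs`).
    """
    out: set[str] = set()
    for a in unified.associations:
        if a.gene not in out and any(
            indication_matches(i, phenotype.synonyms) for i in a.indications
        ):
            out.add(a.gene)
    return out


def classify_target(
    gene: str, phenotype: Phenotype, unified: UnifiedDrugTable
) -> tuple[str, list[RepositioningCall]]:
    """Replicated iff ANY drug targeting the gene lists a matching indication.

    Adding a matching indication can only flip novel → replicated, never the
    reverse.  Empty indication sets match vacuously nothing, so a gene whose
    only drugs carry no indications is novel.
    """
    assocs = unified.gene_index.get(gene)
    if not assocs:
        raise ValueError(f"gene {gene} is not a target in the unified table")
    # pool indications per drug across sources (gene-local view)
    by_drug: dict[str, set[str]] = {}
    for a in assocs:
        by_drug.setdefault(a.drug_key, set()).update(a.indications)
    replicated = any(
        indication_matches(ind, phenotype.synonyms)
        for inds in by_drug.values()
        for ind in inds
    )
    verdict = "replicated" if replicated else "novel"
    calls = [
        RepositioningCall(
            drug_key=drug,
            gene=gene,
            phenotype=phenotype.code,
            current_indications=frozenset(inds),
            status=unified.drugs[drug].status if drug in unified.drugs else "unknown",
            verdict=(
                "replicated"
                if any(indication_matches(i, phenotype.synonyms) for i in inds)
                else "novel"
            ),
        )
        for drug, inds in sorted(by_drug.items())
    ]
    return verdict, calls


def drug_indicated_for(drug_key: str, phenotype: Phenotype, unified: UnifiedDrugTable) -> bool:
    """True if any association of the drug (any gene, any source) lists an
    indication matching the phenotype."""
    inds = unified.drug_indications.get(drug_key, frozenset())
    return any(indication_matches(i, phenotype.synonyms) for i in inds)


def enumerate_novel_drugs(
    novel_targets: Iterable[str], phenotype: Phenotype, unified: UnifiedDrugTable
) -> tuple[set[str], list[RepositioningCall]]:
    """Drugs hitting any novel target, minus drugs already indicated for the
    phenotype (via any of their targets)."""
    novel = set(novel_targets)
    drug_inds = unified.drug_indications
    hits: dict[str, set[str]] = {}  # drug -> novel genes hit
    for g in novel:
        for a in unified.gene_index.get(g, ()):
            hits.setdefault(a.drug_key, set()).add(g)
    selected = set(hits) - indicated_drugs(phenotype, unified)
    calls = [
        RepositioningCall(
            drug_key=d,
            gene=g,
            phenotype=phenotype.code,
            current_indications=frozenset(drug_inds[d]),
            status=unified.drugs[d].status if d in unified.drugs else "unknown",
            verdict="novel",
        )
        for d in sorted(selected)
        for g in sorted(hits[d])
    ]
    return selected, calls


class StatusCounts(NamedTuple):
    AT: int  # targets with >=1 approved drug
    NAT: int  # ... restricted to novel targets
    CT: int  # targets with >=1 drug in a clinical phase
    NCT: int  # ... restricted to novel targets


def stratify_status(
    targets: Iterable[str],
    replicated: Iterable[str],
    unified: UnifiedDrugTable,
) -> StatusCounts:
    """Count approved/clinical targets and their novel subsets.

    A target is approved if any associated drug is approved, clinical if any
    associated drug is in a clinical phase; a target may count in both.
    Unknown-status drugs contribute to neither stratum.
    """
    targets = set(targets)
    replicated = set(replicated)
    status_by_gene: dict[str, set[str]] = {g: set() for g in targets}
    for g in targets:
        for a in unified.gene_index.get(g, ()):
            rec = unified.drugs.get(a.drug_key)
            if rec is not None:
                status_by_gene[g].add(rec.status)
    at = {g for g, st in status_by_gene.items() if "approved" in st}
    ct = {g for g, st in status_by_gene.items() if "clinical" in st}
    return StatusCounts(
        AT=len(at),
        NAT=len(at - replicated),
        CT=len(ct),
        NCT=len(ct - replicated),
    )


# ---------------------------------------------------------------------------
# per-phenotype report
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTargetReport:
    """One summary row per phenotype: counts, ratios, status strata."""

    phenotype: str
    n_candidates: int
    TT: int
    TI: RatioValue | None
    RTT: int
    NTT: int
    NV: RatioValue | None  # None when TT == 0 (undefined)
    status: StatusCounts
    per_source_targets: dict[str, int] = field(default_factory=dict)
    replicated_targets: frozenset[str] = frozenset()
    novel_targets: frozenset[str] = frozenset()
    rank_ti: int | None = None
    rank_nv: int | None = None

    def __post_init__(self) -> None:
        assert self.TT == self.RTT + self.NTT, "TT must equal RTT + NTT"
        assert self.status.NAT <= self.status.AT and self.status.NCT <= self.status.CT


def build_phenotype_report(
    phenotype: Phenotype,
    candidates: Iterable[str],
    unified: UnifiedDrugTable,
) -> PhenotypeTargetReport:
    """Assemble the full per-phenotype row from the candidate union."""
    candidates = set(candidates)
    targets = map_candidates_to_targets(candidates, unified)
    replicated = targets & replicated_target_set(phenotype, unified)
    novel = targets - replicated
    tt = len(targets)
    per_source = {
        s: len(targets & genes) for s, genes in unified.targets_by_source().items()
    }
    return PhenotypeTargetReport(
        phenotype=phenotype.code,
        n_candidates=len(candidates),
        TT=tt,
        TI=targetability_index(tt, len(candidates)) if candidates else None,
        RTT=len(replicated),
        NTT=len(novel),
        NV=novelty_ratio(len(novel), tt) if tt else None,
        status=stratify_status(targets, replicated, unified),
        per_source_targets=per_source,
        replicated_targets=frozenset(replicated),
        novel_targets=frozenset(novel),
    )


def competition_ranks(values: Sequence[float]) -> list[int]:
    """Descending competition ranking ('1224'): ties share a rank, the next
    rank is skipped."""
    order = sorted(values, reverse=True)
    return [order.index(v) + 1 for v in values]


def assign_ranks(reports: Sequence[PhenotypeTargetReport]) -> None:
    """Fill rank_ti / rank_nv across a set of phenotype reports in place."""
    ti = [r.TI.rounded if r.TI else 0.0 for r in reports]
    nv = [r.NV.rounded if r.NV else 0.0 for r in reports]
    for r, rt, rn in zip(reports, competition_ranks(ti), competition_ranks(nv)):
        r.rank_ti, r.rank_nv = rt, rn


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def reports_to_frame(reports: Sequence[PhenotypeTargetReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "phenotype": r.phenotype,
                "n_candidates": r.n_candidates,
                "TT": r.TT,
                "TI": "" if r.TI is None else f"{r.TI.rounded:.2f}",
                "rank_TI": r.rank_ti if r.rank_ti is not None else "",
                "RTT": r.RTT,
                "NTT": r.NTT,
                "NV": "" if r.NV is None else f"{r.NV.rounded:.2f}",
                "rank_NV": r.rank_nv if r.rank_nv is not None else "",
                "AT": r.status.AT,
                "NAT": r.status.NAT,
                "CT": r.status.CT,
                "NCT": r.status.NCT,
            }
        )
    return pd.DataFrame(rows)


def calls_to_frame(calls: Sequence[RepositioningCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "phenotype": c.phenotype,
                "gene": c.gene,
                "drug_key": c.drug_key,
                "status": c.status,
                "current_indications": "|".join(sorted(c.current_indications)),
                "verdict": c.verdict,
            }
            for c in calls
        ],
        columns=["phenotype", "gene", "drug_key", "status", "current_indications", "verdict"],
    )
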
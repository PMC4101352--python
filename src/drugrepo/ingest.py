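"""Ingestion of heterogeneous drug–target association sources.

Three source dialects are supported, modelled on the export formats of the
large public drug knowledge bases:

``drugbank_like``
    one drug–gene pair per row, with brand-name synonyms, a species flag,
    an action and an indication string.
``pharmgkb_like``
    one drug per row with a ``|``-separated list of associated genes and a
    free-text description carrying the disease information.
``ttd_like``
    one drug–target pair per row where the target may be given either as a
    gene symbol or as a UniProt accession that must be resolved through the
    alias map.

All parsers emit the same normalized :class:`TargetAssociation` rows plus a
registry of :class:`DrugRecord` entries, so that downstream code never needs
to know which dialect a row came from.
"""

from __future__ import annotations

import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DIALECTS = ("drugbank_like", "pharmgkb_like", "ttd_like")

DIALECT_COLUMNS: dict[str, tuple[str, ...]] = {
    "drugbank_like": (
        "drug_id",
        "drug_name",
        "brand_names",
        "gene_symbol",
        "species",
        "action",
        "indication",
        "status",
    ),
    "pharmgkb_like": ("drug_name", "associated_genes", "description"),
    "ttd_like": ("drug_name", "target_uniprot_or_symbol", "disease", "status", "action"),
}

#: development-status categories, least to most advanced
STATUS_LEVELS = ("unknown", "discontinued", "preclinical", "clinical", "approved")
_STATUS_RANK = {s: i for i, s in enumerate(STATUS_LEVELS)}

# Looks like a UniProt accession (e.g. P35354, Q9Y6K9, A0A024R161 prefix forms).
_UNIPROT_RE = re.compile(
    r"^(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)


def classify_status(text: str) -> str:
    """Collapse free-text development status into one of ``STATUS_LEVELS``.

    'Discontinued in phase I' counts as discontinued, 'Preclinical' as
    preclinical (checked before the generic 'clinical' match), 'Launched'
    as approved.
    """
    t = text.strip().lower()
    if not t:
        return "unknown"
    if "discontinu" in t or "withdrawn" in t or "terminated" in t:
        return "discontinued"
    if "preclinical" in t or "pre-clinical" in t:
        return "preclinical"
    if "approved" in t or "launched" in t:
        return "approved"
    if "phase" in t or "clinical" in t or "trial" in t or "investigational" in t:
        return "clinical"
    return "unknown"


def most_advanced_status(a: str, b: str) -> str:
    return a if _STATUS_RANK[a] >= _STATUS_RANK[b] else b


# ---------------------------------------------------------------------------
# gene and drug identity
# ---------------------------------------------------------------------------


def load_alias_map(path: str | Path) -> dict[str, str]:
    """Read an alias TSV ([input_token, canonical_symbol]) into a lookup.

    Keys and values are upper-cased and trimmed.  A map whose canonical
    side is itself a (non-identity) alias key would break single-hop
    resolution and idempotence, so such chains are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("input_token", "canonical_symbol"):
        if col not in df.columns:
            raise ValueError(f"alias map {path}: missing mandatory column '{col}'")
    amap: dict[str, str] = {}
    for row in df.itertuples(index=False):
        key = row.input_token.strip().upper()
        val = row.canonical_symbol.strip().upper()
        if not key or not val:
            raise ValueError(f"alias map {path}: empty token in row {row}")
        if key in amap and amap[key] != val:
            raise ValueError(f"alias map {path}: conflicting mappings for '{key}'")
        amap[key] = val
    for key, val in amap.items():
        if val in amap and amap[val] != val:
            raise ValueError(
                f"alias map: chained alias '{key}' -> '{val}' -> '{amap[val]}'; "
                "canonical symbols must be fixed points"
            )
    return amap


def normalize_gene_symbol(token: str, alias_map: Mapping[str, str] | None = None) -> str:
    """Normalize a raw gene token: trim, upper-case, one alias-map hop.

    Idempotent for any valid alias map (canonical symbols are fixed points).
    Raises ``ValueError`` on empty/whitespace-only tokens.
    """
    sym = token.strip().upper()
    if not sym:
        raise ValueError(f"empty gene symbol token: {token!r}")
    if alias_map:
        sym = alias_map.get(sym, sym)
    return sym


def canonical_drug_key(name: str) -> str:
    """Case-insensitive drug identity: trim, collapse internal whitespace, lower."""
    return " ".join(name.split()).lower()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TargetAssociation:
    """One drug → gene link as asserted by one source."""

    drug_key: str
    gene: str
    source: str
    species: str = "human"  # 'human' or 'nonhuman'
    action: str = "unknown"
    indications: frozenset[str] = frozenset()
    status: str = "unknown"  # one of STATUS_LEVELS
    status_text: str = ""

    def __post_init__(self) -> None:
        if self.species not in ("human", "nonhuman"):
            raise ValueError(f"species must be human/nonhuman, got {self.species!r}")
        if self.status not in _STATUS_RANK:
            raise ValueError(f"unknown status category {self.status!r}")


@dataclass
class DrugRecord:
    """A drug with its name synonyms, best known status and provenance."""

    drug_key: str
    names: set[str] = field(default_factory=set)
    status: str = "unknown"
    status_text: str = ""
    sources: set[str] = field(default_factory=set)

    def merge(self, other: "DrugRecord") -> None:
        assert other.drug_key == self.drug_key
        self.names |= other.names
        self.sources |= other.sources
        if _STATUS_RANK[other.status] > _STATUS_RANK[self.status]:
            self.status = other.status
            self.status_text = other.status_text


@dataclass
class ParseReport:
    """Row accounting for one parsed source file."""

    source: str
    n_rows: int = 0  # physical file rows
    n_units: int = 0  # candidate (drug, gene) units scanned (>= n_rows for multi-gene rows)
    n_associations: int = 0
    n_malformed: int = 0
    n_rejected: int = 0
    n_duplicates: int = 0
    rejected_rows: list[tuple[int, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return self.n_rejected == 0 and self.n_malformed == 0


@dataclass
class ParsedSource:
    source: str
    associations: list[TargetAssociation]
    drugs: dict[str, DrugRecord]
    report: ParseReport


@dataclass
class UnifiedDrugTable:
    """Deduplicated union of all source associations plus a drug registry.

    Treated as immutable after construction; lookup indexes are built lazily
    and cached.
    """

    associations: list[TargetAssociation]
    drugs: dict[str, DrugRecord]

    @property
    def targets(self) -> set[str]:
        return {a.gene for a in self.associations}

    @property
    def gene_index(self) -> dict[str, list[TargetAssociation]]:
        """gene → its associations (built once)."""
        cached = getattr(self, "_gene_index", None)
        if cached is None:
            cached = {}
            for a in self.associations:
                cached.setdefault(a.gene, []).append(a)
            self._gene_index = cached
        return cached

    @property
    def drug_indications(self) -> dict[str, frozenset[str]]:
        """drug_key → indications pooled over all its associations."""
        cached = getattr(self, "_drug_indications", None)
        if cached is None:
            pool: dict[str, set[str]] = {}
            for a in self.associations:
                pool.setdefault(a.drug_key, set()).update(a.indications)
            cached = {d: frozenset(s) for d, s in pool.items()}
            self._drug_indications = cached
        return cached

    @property
    def sources(self) -> tuple[str, ...]:
        return tuple(sorted({a.source for a in self.associations}))

    def targets_by_source(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.sources}
        for a in self.associations:
            out[a.source].add(a.gene)
        return out

    def drugs_by_source(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {s: set() for s in self.sources}
        for a in self.associations:
            out[a.source].add(a.drug_key)
        return out

    def associations_for_gene(self, gene: str) -> list[TargetAssociation]:
        return list(self.gene_index.get(gene, ()))


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, dialect: str, path: str | Path) -> None:
    for col in DIALECT_COLUMNS[dialect]:
        if col not in df.columns:
            raise ValueError(f"{path}: dialect '{dialect}' requires missing column '{col}'")


def _register_drug(
    drugs: dict[str, DrugRecord],
    name: str,
    source: str,
    status: str = "unknown",
    status_text: str = "",
    extra_names: Iterable[str] = (),
) -> str:
    key = canonical_drug_key(name)
    names = {" ".join(name.split())} | {" ".join(n.split()) for n in extra_names if n.strip()}
    rec = DrugRecord(drug_key=key, names=names, status=status, status_text=status_text, sources={source})
    if key in drugs:
        drugs[key].merge(rec)
    else:
        drugs[key] = rec
    return key


def parse_source(
    path: str | Path,
    dialect: str,
    alias_map: Mapping[str, str] | None = None,
    source_id: str | None = None,
) -> ParsedSource:
    """Parse one source TSV into normalized associations and a drug registry.

    Malformed rows (empty drug or gene fields) and unmappable target
    identifiers are quarantined into the :class:`ParseReport`, never silently
    dropped.  Duplicate (drug, gene) rows within the source are merged, with
    indication/action union, and counted.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    source = source_id or dialect
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, dialect, path)

    report = ParseReport(source=source, n_rows=len(df))
    drugs: dict[str, DrugRecord] = {}
    # (drug_key, gene) -> mutable accumulator for within-source dedup
    acc: dict[tuple[str, str], dict] = {}

    def reject(i: int, reason: str, malformed: bool = False) -> None:
        report.n_rejected += 1
        if malformed:
            report.n_malformed += 1
        report.rejected_rows.append((i, reason))

    def add(
        i: int,
        drug_name: str,
        gene_token: str,
        *,
        species: str = "human",
        action: str = "",
        indication: str = "",
        status_text: str = "",
        brand_names: Iterable[str] = (),
        resolve_accession: bool = False,
    ) -> None:
        report.n_units += 1
        if not drug_name.strip():
            reject(i, "empty drug name", malformed=True)
            return
        token = gene_token.strip().upper()
        if not token:
            reject(i, "empty gene/target field", malformed=True)
            return
        if resolve_accession and _UNIPROT_RE.match(token) and (not alias_map or token not in alias_map):
            reject(i, f"unmappable target identifier '{gene_token.strip()}'")
            return
        gene = normalize_gene_symbol(token, alias_map)
        status = classify_status(status_text)
        key = _register_drug(drugs, drug_name, source, status, status_text, brand_names)
        slot = acc.setdefault(
            (key, gene),
            {
                "species": species,
                "action": "unknown",
                "indications": set(),
                "status": "unknown",
                "status_text": "",
                "n": 0,
            },
        )
        slot["n"] += 1
        if action.strip() and slot["action"] == "unknown":
            slot["action"] = action.strip().lower()
        if indication.strip():
            slot["indications"].add(indication.strip())
        if _STATUS_RANK[status] > _STATUS_RANK[slot["status"]]:
            slot["status"], slot["status_text"] = status, status_text
        # a row flagged nonhuman marks the association nonhuman
        if species == "nonhuman":
            slot["species"] = "nonhuman"

    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        if dialect == "drugbank_like":
            species = "human" if row.species.strip().lower() == "human" else "nonhuman"
            brands = [b for b in row.brand_names.split("|") if b.strip()]
            add(
                i,
                row.drug_name,
                row.gene_symbol,
                species=species,
                action=row.action,
                indication=row.indication,
                status_text=row.status,
                brand_names=brands,
            )
        elif dialect == "pharmgkb_like":
            genes = [g for g in row.associated_genes.split("|") if g.strip()]
            if not genes:
                report.n_units += 1
                reject(i, "empty gene/target field", malformed=True)
                continue
            for g in genes:
                add(i, row.drug_name, g, indication=row.description)
        else:  # ttd_like
            add(
                i,
                row.drug_name,
                row.target_uniprot_or_symbol,
                action=row.action,
                indication=row.disease,
                status_text=row.status,
                resolve_accession=True,
            )

    associations = [
        TargetAssociation(
            drug_key=key,
            gene=gene,
            source=source,
            species=slot["species"],
            action=slot["action"],
            indications=frozenset(slot["indications"]),
            status=slot["status"],
            status_text=slot["status_text"],
        )
        for (key, gene), slot in sorted(acc.items())
    ]
    report.n_associations = len(associations)
    report.n_duplicates = sum(slot["n"] - 1 for slot in acc.values())
    if report.n_duplicates:
        logger.info("%s: merged %d duplicate rows", source, report.n_duplicates)
    if report.n_rejected:
        logger.warning("%s: quarantined %d rows", source, report.n_rejected)
    return ParsedSource(source=source, associations=associations, drugs=drugs, report=report)


def filter_human(associations: Sequence[TargetAssociation]) -> list[TargetAssociation]:
    """Keep only associations whose species flag is human."""
    kept = [a for a in associations if a.species == "human"]
    logger.info("human filter: %d associations in, %d retained", len(associations), len(kept))
    return kept


# ---------------------------------------------------------------------------
# merging and overlap statistics
# ---------------------------------------------------------------------------


def merge_sources(parsed: Sequence[ParsedSource | tuple]) -> UnifiedDrugTable:
    """Merge per-source tables into one deduplicated table.

    Order-invariant: associations are deduplicated on (drug_key, gene, source)
    and sorted; drug registries are merged on the canonical name key with
    union of synonyms/sources and the most advanced status kept (conflicts
    logged).
    """
    assoc: dict[tuple[str, str, str], TargetAssociation] = {}
    drugs: dict[str, DrugRecord] = {}
    for ps in parsed:
        if isinstance(ps, tuple):  # (associations, drugs) pair also accepted
            ps_assoc, ps_drugs = ps
        else:
            ps_assoc, ps_drugs = ps.associations, ps.drugs
        for a in ps_assoc:
            k = (a.drug_key, a.gene, a.source)
            if k in assoc:
                prev = assoc[k]
                assoc[k] = replace(
                    prev,
                    indications=prev.indications | a.indications,
                    status=most_advanced_status(prev.status, a.status),
                )
            else:
                assoc[k] = a
        for key in sorted(ps_drugs):
            rec = ps_drugs[key]
            if key in drugs:
                if (
                    drugs[key].status != rec.status
                    and drugs[key].status != "unknown"
                    and rec.status != "unknown"
                ):
                    logger.info(
                        "status conflict for drug '%s': %s vs %s, keeping most advanced",
                        key,
                        drugs[key].status,
                        rec.status,
                    )
                drugs[key].merge(
                    DrugRecord(
                        drug_key=rec.drug_key,
                        names=set(rec.names),
                        status=rec.status,
                        status_text=rec.status_text,
                        sources=set(rec.sources),
                    )
                )
            else:
                drugs[key] = DrugRecord(
                    drug_key=rec.drug_key,
                    names=set(rec.names),
                    status=rec.status,
                    status_text=rec.status_text,
                    sources=set(rec.sources),
                )
    table = UnifiedDrugTable(associations=[assoc[k] for k in sorted(assoc)], drugs=drugs)
    missing = {a.drug_key for a in table.associations} - set(drugs)
    assert not missing, f"associations reference unregistered drugs: {missing}"
    return table


@dataclass
class VennCounts:
    """Region counts for up to three overlapping sets keyed by source id."""

    sources: tuple[str, ...]
    per_source: dict[str, int]
    unique_per_source: dict[str, int]
    pairwise_shared: dict[tuple[str, str], int]  # raw |A ∩ B|
    pairwise_exclusive: dict[tuple[str, str], int]  # |A ∩ B| minus the triple core
    triple_shared: int
    union: int

    @classmethod
    def from_sets(cls, sets: Mapping[str, set[str]]) -> "VennCounts":
        names = tuple(sorted(sets))
        union = set().union(*sets.values()) if sets else set()
        per = {s: len(sets[s]) for s in names}
        uniq = {
            s: len(sets[s] - set().union(*(sets[t] for t in names if t != s)))
            if len(names) > 1
            else len(sets[s])
            for s in names
        }
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        raw = {(a, b): len(sets[a] & sets[b]) for a, b in pairs}
        if len(names) == 3:
            triple = len(sets[names[0]] & sets[names[1]] & sets[names[2]])
        else:
            triple = 0
        excl = {p: raw[p] - triple for p in raw}
        vc = cls(
            sources=names,
            per_source=per,
            unique_per_source=uniq,
            pairwise_shared=raw,
            pairwise_exclusive=excl,
            triple_shared=triple,
            union=len(union),
        )
        vc._assert_inclusion_exclusion()
        return vc

    def _assert_inclusion_exclusion(self) -> None:
        if len(self.sources) == 3:
            expect = (
                sum(self.per_source.values())
                - sum(self.pairwise_shared.values())
                + self.triple_shared
            )
        elif len(self.sources) == 2:
            expect = sum(self.per_source.values()) - sum(self.pairwise_shared.values())
        else:
            expect = sum(self.per_source.values())
        assert expect == self.union, (
            f"inclusion-exclusion violated: expected union {expect}, got {self.union}"
        )

    def to_dict(self) -> dict:
        return {
            "sources": list(self.sources),
            "per_source": dict(self.per_source),
            "unique_per_source": dict(self.unique_per_source),
            "pairwise_shared": {"|".join(k): v for k, v in self.pairwise_shared.items()},
            "pairwise_exclusive": {"|".join(k): v for k, v in self.pairwise_exclusive.items()},
            "triple_shared": self.triple_shared,
            "union": self.union,
        }


@dataclass
class OverlapReport:
    """Cross-source coverage/overlap statistics for targets and drugs."""

    targets: VennCounts
    drugs: VennCounts
    genome_size: int
    genome_coverage: float

    # convenience aliases used throughout reports
    @property
    def union_targets(self) -> int:
        return self.targets.union

    @property
    def triple_shared(self) -> int:
        return self.targets.triple_shared

    def to_dict(self) -> dict:
        return {
            "targets": self.targets.to_dict(),
            "drugs": self.drugs.to_dict(),
            "genome_size": self.genome_size,
            "genome_coverage": self.genome_coverage,
        }


def overlap_stats(unified: UnifiedDrugTable, genome_size: int) -> OverlapReport:
    """Compute Venn-region counts over sources for targets and drugs.

    The inclusion–exclusion identity is asserted internally on the underlying
    sets before the report is returned.  ``genome_size`` smaller than the
    target union is a hard error (coverage would exceed 1).
    """
    if not unified.sources:
        raise ValueError("overlap_stats requires at least one source")
    tsets = unified.targets_by_source()
    dsets = unified.drugs_by_source()
    targets = VennCounts.from_sets(tsets)
    drugs = VennCounts.from_sets(dsets)
    if genome_size < targets.union:
        raise ValueError(
            f"genome_size {genome_size} < union of targets {targets.union}: coverage > 1"
        )
    return OverlapReport(
        targets=targets,
        drugs=drugs,
        genome_size=genome_size,
        genome_coverage=targets.union / genome_size,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_UNIFIED_COLUMNS = (
    "source",
    "drug_key",
    "gene",
    "species",
    "action",
    "status",
    "status_text",
    "indications",
)


def write_unified_table(unified: UnifiedDrugTable, path: str | Path) -> None:
    """Write the unified table as a TSV plus a JSON sidecar.

    The sidecar carries the drug registry (synonyms, statuses, provenance)
    and per-source row counts so that a read-back reproduces the table
    exactly (round-trip fixed point).
    """
    path = Path(path)
    rows = [
        {
            "source": a.source,
            "drug_key": a.drug_key,
            "gene": a.gene,
            "species": a.species,
            "action": a.action,
            "status": a.status,
            "status_text": a.status_text,
            "indications": "|".join(sorted(a.indications)),
        }
        for a in unified.associations
    ]
    df = pd.DataFrame(rows, columns=_UNIFIED_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    sidecar = {
        "per_source_associations": dict(Counter(a.source for a in unified.associations)),
        "n_targets": len(unified.targets),
        "n_drugs": len(unified.drugs),
        "drugs": {
            k: {
                "names": sorted(r.names),
                "status": r.status,
                "status_text": r.status_text,
                "sources": sorted(r.sources),
            }
            for k, r in sorted(unified.drugs.items())
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_unified_table(path: str | Path) -> UnifiedDrugTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    associations = [
        TargetAssociation(
            drug_key=r.drug_key,
            gene=r.gene,
            source=r.source,
            species=r.species,
            action=r.action,
            indications=frozenset(x for x in r.indications.split("|") if x),
            status=r.status,
            status_text=r.status_text,
        )
        for r in df.itertuples(index=False)
    ]
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    drugs = {
        k: DrugRecord(
            drug_key=k,
            names=set(v["names"]),
            status=v["status"],
            status_text=v["status_text"],
            sources=set(v["sources"]),
        )
        for k, v in sidecar["drugs"].items()
    }
    return UnifiedDrugTable(associations=sorted(associations, key=lambda a: (a.drug_key, a.gene, a.source)), drugs=drugs)
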
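"""Reference-library audit: per-species divergence summaries, barcode-gap
flags, deep haplotype clusters, diagnostic nucleotides, rule-based name
assignment, discordance screening and report tables.

Terminology follows common barcoding usage:

* **MXID** — maximum intraspecific K2P distance of a species.
* **MNID** — minimum K2P distance from any specimen of the species to any
  specimen of a *different* species within the comparison scope
  (congeners by default).
* **barcode-gap overlap** — MXID > MNID, which undermines distance-based
  identification for that species.
* **deep clusters** — single-linkage haplotype clusters within a species
  separated by more than the split threshold (5% by default); two or more
  such clusters mark a candidate cryptic species complex.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .distance import (
    DEFAULT_MIN_OVERLAP,
    DistanceMatrix,
    build_distance_matrix,
    detect_shared_haplotypes,
    k2p_distance,
    single_linkage_clusters,
)
from .seq_io_qc import (
    DEFAULT_MIN_LENGTH,
    AnchoredSequence,
    SpecimenRecord,
    apply_qc,
)
from .tree import (
    MonophylyStatus,
    classify_species_monophyly,
    midpoint_root,
    neighbor_joining,
    write_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AuditConfig",
    "SpeciesAuditSummary",
    "DiagnosticCharacter",
    "Assignment",
    "DiscordantSpecimen",
    "ProvisionalNameRegistry",
    "AuditResult",
    "species_pairwise_summary",
    "flag_species",
    "count_deep_clusters",
    "find_diagnostic_positions",
    "assign_specimen",
    "make_provisional_name",
    "flag_discordant_specimens",
    "summarize_library",
    "run_audit",
    "format_percent",
]


@dataclass(frozen=True)
class AuditConfig:
    """Thresholds of the audit, as K2P proportions.

    ``t_deep`` flags species whose MXID exceeds the level commonly taken to
    delimit insect species (2.2%); ``t_split`` separates deep haplotype
    clusters (5%); ``t_assign`` is the name-propagation radius (<2%).
    """

    t_deep: float = 0.022
    t_split: float = 0.050
    t_assign: float = 0.020
    mnid_scope: str = "genus"  # genus | family | all
    min_overlap: int = DEFAULT_MIN_OVERLAP
    min_len: int = DEFAULT_MIN_LENGTH

    def __post_init__(self) -> None:
        if not (0 < self.t_assign < 1 and 0 < self.t_deep < self.t_split < 1):
            raise ValueError("thresholds must satisfy 0 < t_assign, t_deep < t_split < 1")
        if self.mnid_scope not in ("genus", "family", "all"):
            raise ValueError(f"bad mnid_scope {self.mnid_scope!r}")


@dataclass
class SpeciesAuditSummary:
    species_label: str
    n_specimens: int
    mxid: float | None  # max intraspecific distance; None for singletons
    mean_intra: float | None
    n_intra_pairs: int
    mnid: float | None  # min distance to another species in scope
    nearest_neighbor_species: str | None
    n_clusters_at_split: int
    monophyly: MonophylyStatus | None = None
    flags: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class DiagnosticCharacter:
    species_label: str
    position: int  # 1-based site on the 658 frame
    state: str


@dataclass(frozen=True)
class Assignment:
    specimen_id: str
    status: str  # assigned | ambiguous | unassigned
    species_label: str | None
    candidates: tuple[str, ...]
    min_distance: float | None
    confidence: str | None  # "propagated" when assigned


@dataclass(frozen=True)
class DiscordantSpecimen:
    specimen_id: str
    labeled_species: str
    nearest_neighbor_id: str
    nearest_neighbor_species: str
    d_nearest: float
    d_own_species: float | None  # None for singletons (vacuously distant)


def format_percent(d: float | None, decimals: int = 1) -> str:
    """Render a proportion as percent; undefined values as an en dash."""
    if d is None or (isinstance(d, float) and math.isnan(d)):
        return "–"
    return f"{100.0 * d:.{decimals}f}"


# ---------------------------------------------------------------------------
# Per-species summaries


def _scope_key(record: SpecimenRecord, scope: str) -> str:
    if scope == "genus":
        return record.genus
    if scope == "family":
        return record.family
    return "__all__"


def species_pairwise_summary(
    matrix: DistanceMatrix,
    records: Mapping[str, SpecimenRecord],
    config: AuditConfig = AuditConfig(),
) -> list[SpeciesAuditSummary]:
    """MXID / mean-intra / MNID / nearest neighbor / deep-cluster count per species.

    Specimens with ``id_confidence == "unidentified"`` are excluded.
    Undefined (saturated or under-overlap) pairs are skipped with a logged
    warning and do not contribute to any statistic.
    """
    ids = [i for i in matrix.ids if records[i].id_confidence != "unidentified"]
    missing = [i for i in matrix.ids if i not in records]
    if missing:
        raise ValueError(f"specimens absent from metadata: {missing[:5]}")

    by_species: dict[str, list[str]] = {}
    for sid in ids:
        by_species.setdefault(records[sid].species_label, []).append(sid)

    n_undefined = 0
    out = []
    for species in sorted(by_species):
        members = by_species[species]
        scope_val = _scope_key(records[members[0]], config.mnid_scope)

        intra = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                d = matrix.get(a, b)
                if math.isnan(d):
                    n_undefined += 1
                else:
                    intra.append(d)
        mxid = max(intra) if intra else None
        mean_intra = sum(intra) / len(intra) if intra else None

        mnid = None
        nn_species = None
        for other in ids:
            rec = records[other]
            if rec.species_label == species:
                continue
            if _scope_key(rec, config.mnid_scope) != scope_val:
                continue
            for a in members:
                d = matrix.get(a, other)
                if math.isnan(d):
                    n_undefined += 1
                    continue
                if mnid is None or d < mnid or (d == mnid and rec.species_label < nn_species):
                    mnid = d
                    nn_species = rec.species_label
        n_clusters, _ = count_deep_clusters(matrix, members, config.t_split)
        summary = SpeciesAuditSummary(
            species_label=species,
            n_specimens=len(members),
            mxid=mxid,
            mean_intra=mean_intra,
            n_intra_pairs=len(intra),
            mnid=mnid,
            nearest_neighbor_species=nn_species,
            n_clusters_at_split=n_clusters,
        )
        out.append(flag_species(summary, config))
    if n_undefined:
        logger.warning(
            "%d undefined pairwise distances were excluded from species summaries",
            n_undefined,
        )
    return out


def flag_species(summary: SpeciesAuditSummary, config: AuditConfig) -> SpeciesAuditSummary:
    """Set deep_divergence / multi_cluster / gap_overlap flags (strict >)."""
    flags = set()
    if summary.mxid is not None and summary.mxid > config.t_deep:
        flags.add("deep_divergence")
    if summary.n_clusters_at_split >= 2:
        flags.add("multi_cluster")
    if (
        summary.mxid is not None
        and summary.mnid is not None
        and summary.mxid > summary.mnid
    ):
        flags.add("gap_overlap")
    summary.flags = flags
    return summary


def count_deep_clusters(
    matrix: DistanceMatrix, members: Sequence[str], t_split: float
) -> tuple[int, list[list[str]]]:
    """Single-linkage haplotype clusters among one species' specimens."""
    if len(members) == 1:
        return 1, [list(members)]
    clusters = single_linkage_clusters(matrix, members, cutoff=t_split)
    return len(clusters), clusters


# ---------------------------------------------------------------------------
# Diagnostic nucleotides


def find_diagnostic_positions(
    seqs: Sequence[AnchoredSequence],
    species_of: Mapping[str, str],
    species_set: Sequence[str],
    min_coverage: int = 1,
) -> list[DiagnosticCharacter]:
    """Fixed nucleotide differences distinguishing species of ``species_set``.

    A (position, state) is diagnostic for species s iff every member of s
    with a concrete base at the position carries the state, no member of
    any other species in the set with a concrete base there carries it, and
    at least ``min_coverage`` members of s have data at the position.
    Output is sorted by species then position (1-based frame coordinates).
    """
    species_set = list(dict.fromkeys(species_set))
    if len(species_set) < 2:
        raise ValueError("need at least two species to diagnose")
    groups: dict[str, list[np.ndarray]] = {s: [] for s in species_set}
    for seq in seqs:
        sp = species_of.get(seq.specimen_id)
        if sp in groups:
            groups[sp].append(seq.frame_codes())
    empty = [s for s, g in groups.items() if not g]
    if empty:
        raise ValueError(f"no sequences for species: {', '.join(empty)}")
    mats = {s: np.stack(g) for s, g in groups.items()}

    out: list[DiagnosticCharacter] = []
    frame_len = next(iter(mats.values())).shape[1]
    for species in species_set:
        own = mats[species]
        others = np.vstack([mats[s] for s in species_set if s != species])
        for pos in range(frame_len):
            col = own[:, pos]
            col = col[col < 4]
            if col.size < min_coverage or col.size == 0:
                continue
            state = col[0]
            if not np.all(col == state):
                continue
            other_col = others[:, pos]
            other_col = other_col[other_col < 4]
            if np.any(other_col == state):
                continue
            out.append(
                DiagnosticCharacter(
                    species_label=species,
                    position=pos + 1,
                    state="ACGT"[state],
                )
            )
    out.sort(key=lambda c: (species_set.index(c.species_label), c.position))
    return out


# ---------------------------------------------------------------------------
# Name assignment


def assign_specimen(
    query: AnchoredSequence,
    references: Sequence[tuple[AnchoredSequence, str]],
    config: AuditConfig = AuditConfig(),
) -> Assignment:
    """Propagate a name from expert-identified references within t_assign.

    ``references`` are (sequence, species_label) pairs for expert-identified
    specimens.  The query inherits the single species whose closest
    reference lies at d < t_assign; several such species -> ambiguous; none
    -> unassigned (a candidate for a provisional name).
    """
    if query.qc_status != "pass":
        raise ValueError(f"query {query.specimen_id!r} failed QC ({query.qc_status})")
    if not references:
        raise ValueError("reference library is empty")
    best: dict[str, float] = {}
    for ref, species in references:
        comp = k2p_distance(query, ref, min_overlap=config.min_overlap)
        if not comp.defined:
            continue
        if species not in best or comp.d < best[species]:
            best[species] = comp.d
    hits = sorted(s for s, d in best.items() if d < config.t_assign)
    overall_min = min(best.values()) if best else None
    if len(hits) == 1:
        return Assignment(
            query.specimen_id, "assigned", hits[0], tuple(hits), best[hits[0]], "propagated"
        )
    if len(hits) > 1:
        return Assignment(
            query.specimen_id,
            "ambiguous",
            None,
            tuple(hits),
            min(best[s] for s in hits),
            None,
        )
    return Assignment(query.specimen_id, "unassigned", None, (), overall_min, None)


class ProvisionalNameRegistry:
    """Serial bookkeeping for provisional names like 'Heptagenia sp.LJ1'.

    Previously published names (including the spaced form 'Acerpenna
    sp. CHU1') can be preloaded as reserved, so new names never collide.
    """

    _PARSE = re.compile(r"^([A-Z][A-Za-z]*) sp\. ?([A-Za-z]+)([0-9]+)$")

    def __init__(self, reserved: Iterable[str] = ()):
        self._used: set[tuple[str, str, int]] = set()
        for name in reserved:
            self.reserve(name)

    def reserve(self, label: str) -> None:
        m = self._PARSE.match(label)
        if not m:
            raise ValueError(f"not a provisional name: {label!r}")
        genus, initials, serial = m.groups()
        self._used.add((genus, initials, int(serial)))

    def next_name(self, genus: str, taxonomist_initials: str) -> str:
        serial = 1
        while (genus, taxonomist_initials, serial) in self._used:
            serial += 1
        self._used.add((genus, taxonomist_initials, serial))
        return f"{genus} sp.{taxonomist_initials}{serial}"


def make_provisional_name(
    genus: str, taxonomist_initials: str, registry: ProvisionalNameRegistry
) -> str:
    """Smallest free serial for genus+initials; updates the registry."""
    if not genus:
        raise ValueError("genus must be non-empty")
    return registry.next_name(genus, taxonomist_initials)


# ---------------------------------------------------------------------------
# Discordance screening


def flag_discordant_specimens(
    matrix: DistanceMatrix,
    species_of: Mapping[str, str],
    config: AuditConfig = AuditConfig(),
) -> list[DiscordantSpecimen]:
    """Specimens whose barcode sits with a different species.

    A specimen is flagged iff its nearest neighbor lies at d < t_assign and
    carries a different species label, while its nearest *conspecific* (if
    any) lies beyond t_split.  Both distances are reported so flagged
    records can be re-examined.
    """
    out = []
    ids = matrix.ids
    for i, sid in enumerate(ids):
        own = species_of[sid]
        nn_j = None
        nn_d = math.inf
        own_d = math.inf
        has_conspecific = False
        for j, other in enumerate(ids):
            if i == j:
                continue
            d = matrix.d[i, j]
            if math.isnan(d):
                continue
            if d < nn_d or (d == nn_d and other < ids[nn_j]):
                nn_d, nn_j = d, j
            if species_of[other] == own:
                has_conspecific = True
                own_d = min(own_d, d)
        if nn_j is None:
            continue
        nn_id = ids[nn_j]
        if (
            nn_d < config.t_assign
            and species_of[nn_id] != own
            and (not has_conspecific or own_d > config.t_split)
        ):
            out.append(
                DiscordantSpecimen(
                    specimen_id=sid,
                    labeled_species=own,
                    nearest_neighbor_id=nn_id,
                    nearest_neighbor_species=species_of[nn_id],
                    d_nearest=float(nn_d),
                    d_own_species=None if not has_conspecific else float(own_d),
                )
            )
    return sorted(out, key=lambda f: f.specimen_id)


# ---------------------------------------------------------------------------
# Library rollups


@dataclass
class GlobalStats:
    n_specimens: int
    n_species: int
    mean_specimens_per_species: float
    max_specimens_per_species: int
    mean_mxid: float | None
    mean_intra_all_pairs: float | None
    min_mnid: float | None
    max_mnid: float | None
    mean_mnid: float | None
    pct_deep_divergence: float
    pct_multi_cluster: float
    pct_gap_overlap: float


def summarize_library(
    summaries: Sequence[SpeciesAuditSummary],
    records: Mapping[str, SpecimenRecord],
    checklist: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, GlobalStats]:
    """Family rollup table plus dataset-wide statistics.

    The rollup mirrors a coverage/divergence summary table: known species
    per family (from the optional checklist), barcoded and provisional
    species counts, species flagged for deep divergence, and family means
    of MXID and MNID (en dash where undefined).
    """
    family_of_species: dict[str, str] = {}
    provisional: dict[str, bool] = {}
    for rec in records.values():
        family_of_species[rec.species_label] = rec.family
        provisional[rec.species_label] = rec.is_provisional

    families = sorted(
        {family_of_species[s.species_label] for s in summaries}
        | (set(checklist) if checklist else set())
    )
    rows = []
    for family in families:
        fam_sum = [s for s in summaries if family_of_species.get(s.species_label) == family]
        mxids = [s.mxid for s in fam_sum if s.mxid is not None]
        mnids = [s.mnid for s in fam_sum if s.mnid is not None]
        known = checklist.get(family) if checklist else None
        if checklist is not None and family not in checklist:
            logger.warning("family %s missing from checklist", family)
        rows.append(
            {
                "family": family,
                "n_known_species": "–" if known is None else known,
                "n_barcoded_species": sum(
                    1 for s in fam_sum if not provisional[s.species_label]
                ),
                "n_provisional_species": sum(
                    1 for s in fam_sum if provisional[s.species_label]
                ),
                "n_deep_divergence": sum(
                    1 for s in fam_sum if "deep_divergence" in s.flags
                ),
                "mean_mxid_pct": format_percent(
                    sum(mxids) / len(mxids) if mxids else None
                ),
                "mean_mnid_pct": format_percent(
                    sum(mnids) / len(mnids) if mnids else None
                ),
            }
        )
    rollup = pd.DataFrame(
        rows,
        columns=[
            "family",
            "n_known_species",
            "n_barcoded_species",
            "n_provisional_species",
            "n_deep_divergence",
            "mean_mxid_pct",
            "mean_mnid_pct",
        ],
    )

    counts = [s.n_specimens for s in summaries]
    mxids = [s.mxid for s in summaries if s.mxid is not None]
    mnids = [s.mnid for s in summaries if s.mnid is not None]
    intra_sum = sum(
        (s.mean_intra or 0.0) * s.n_intra_pairs for s in summaries
    )
    intra_n = sum(s.n_intra_pairs for s in summaries)
    multi = [s for s in summaries if s.n_specimens > 1]
    stats = GlobalStats(
        n_specimens=sum(counts),
        n_species=len(summaries),
        mean_specimens_per_species=sum(counts) / len(counts) if counts else 0.0,
        max_specimens_per_species=max(counts) if counts else 0,
        mean_mxid=sum(mxids) / len(mxids) if mxids else None,
        mean_intra_all_pairs=intra_sum / intra_n if intra_n else None,
        min_mnid=min(mnids) if mnids else None,
        max_mnid=max(mnids) if mnids else None,
        mean_mnid=sum(mnids) / len(mnids) if mnids else None,
        pct_deep_divergence=(
            100.0 * sum(1 for s in summaries if "deep_divergence" in s.flags) / len(summaries)
            if summaries
            else 0.0
        ),
        pct_multi_cluster=(
            100.0 * sum(1 for s in multi if "multi_cluster" in s.flags) / len(multi)
            if multi
            else 0.0
        ),
        pct_gap_overlap=(
            100.0 * sum(1 for s in summaries if "gap_overlap" in s.flags) / len(summaries)
            if summaries
            else 0.0
        ),
    )
    return rollup, stats


# ---------------------------------------------------------------------------
# End-to-end audit


@dataclass
class AuditResult:
    summaries: list[SpeciesAuditSummary]
    rollup: pd.DataFrame
    stats: GlobalStats
    matrix: DistanceMatrix
    trees: dict[str, object]  # scope key -> rooted TreeNode
    shared_haplotypes: list[tuple[str, str, str, str]]
    discordant: list[DiscordantSpecimen]
    qc_failures: list[str]

    def species_table(self) -> pd.DataFrame:
        rows = []
        for s in self.summaries:
            rows.append(
                {
                    "species": s.species_label,
                    "n": s.n_specimens,
                    "MXID_pct": format_percent(s.mxid),
                    "mean_intra_pct": format_percent(s.mean_intra),
                    "MNID_pct": format_percent(s.mnid),
                    "nearest_neighbor": s.nearest_neighbor_species or "–",
                    "n_clusters": s.n_clusters_at_split,
                    "monophyly": s.monophyly.status if s.monophyly else "–",
                    "flags": ",".join(sorted(s.flags)) or "–",
                }
            )
        return pd.DataFrame(rows)


def run_audit(
    seqs: Sequence[AnchoredSequence],
    records: Sequence[SpecimenRecord],
    config: AuditConfig = AuditConfig(),
    checklist: Mapping[str, int] | None = None,
    tree_scope: str = "family",
    exclude_discordant: bool = True,
) -> AuditResult:
    """Full audit over a library: QC, distances, summaries, trees, flags.

    Sequences failing QC are excluded.  Discordance screening runs first;
    by default flagged specimens (apparent misidentifications awaiting
    re-examination) are set aside before the per-species summaries and
    trees are computed, since a single mislabelled barcode distorts the
    divergence statistics of two species at once.  Trees are built per
    ``tree_scope`` group (family by default) when at least three specimens
    with fully defined pairwise distances are present; monophyly calls from
    those trees are merged into the per-species summaries.
    """
    record_map = {r.specimen_id: r for r in records}
    seqs, _reports = apply_qc(seqs, min_len=config.min_len)
    kept = [s for s in seqs if s.qc_status == "pass" and s.specimen_id in record_map]
    qc_failures = [s.specimen_id for s in seqs if s.qc_status != "pass"]
    if len(kept) < 2:
        raise ValueError("fewer than 2 sequences survive QC")

    matrix = build_distance_matrix(kept, min_overlap=config.min_overlap)
    species_of = {s.specimen_id: record_map[s.specimen_id].species_label for s in kept}

    shared = detect_shared_haplotypes(matrix, species_of)
    discordant = flag_discordant_specimens(matrix, species_of, config)

    if exclude_discordant and discordant:
        flagged_ids = {f.specimen_id for f in discordant}
        logger.info(
            "excluding %d discordant specimen(s) from summaries pending re-examination",
            len(flagged_ids),
        )
        kept = [s for s in kept if s.specimen_id not in flagged_ids]
        clean_matrix = matrix.submatrix([i for i in matrix.ids if i not in flagged_ids])
    else:
        clean_matrix = matrix

    summaries = species_pairwise_summary(clean_matrix, record_map, config)

    trees: dict[str, object] = {}
    mono: dict[str, MonophylyStatus] = {}
    groups: dict[str, list[str]] = {}
    for s in kept:
        key = _scope_key(record_map[s.specimen_id], tree_scope)
        groups.setdefault(key, []).append(s.specimen_id)
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 3:
            continue
        sub = clean_matrix.submatrix(sorted(members))
        if np.isnan(sub.d).any():
            logger.warning("skipping tree for %s: undefined distances", key)
            continue
        rooted = midpoint_root(neighbor_joining(sub))
        trees[key] = rooted
        for status in classify_species_monophyly(rooted, species_of):
            mono[status.species_label] = status
    for s in summaries:
        s.monophyly = mono.get(s.species_label)

    rollup, stats = summarize_library(summaries, record_map, checklist)
    return AuditResult(
        summaries=summaries,
        rollup=rollup,
        stats=stats,
        matrix=matrix,
        trees=trees,
        shared_haplotypes=shared,
        discordant=discordant,
        qc_failures=qc_failures,
    )


def write_audit_reports(result: AuditResult, outdir: str | Path) -> dict[str, Path]:
    """Write the standard TSV/newick report set for an audit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": outdir / "species_summary.tsv",
        "families": outdir / "family_summary.tsv",
        "flags": outdir / "flags.tsv",
    }
    result.species_table().to_csv(paths["species"], sep="\t", index=False)
    result.rollup.to_csv(paths["families"], sep="\t", index=False)
    flag_rows = [
        {
            "specimen_id": f.specimen_id,
            "labeled_species": f.labeled_species,
            "nearest_neighbor_id": f.nearest_neighbor_id,
            "nearest_neighbor_species": f.nearest_neighbor_species,
            "d_nearest_pct": format_percent(f.d_nearest, 2),
            "d_own_species_pct": format_percent(f.d_own_species, 2),
        }
        for f in result.discordant
    ]
    pd.DataFrame(
        flag_rows,
        columns=[
            "specimen_id",
            "labeled_species",
            "nearest_neighbor_id",
            "nearest_neighbor_species",
            "d_nearest_pct",
            "d_own_species_pct",
        ],
    ).to_csv(paths["flags"], sep="\t", index=False)
    for key, tree in result.trees.items():
        p = outdir / f"tree_{key}.nwk"
        write_newick(tree, p)
        paths[f"tree_{key}"] = p
    return paths
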
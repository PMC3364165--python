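"""Synthetic COI barcode libraries with known truth.

The generator emulates the statistical structure of a multi-species mayfly
barcode library: within-species haplotype radiations around ~2% K2P
divergence, congeneric species separated by ~12%, a configurable fraction
of "cryptic complex" species composed of 2-3 haplotype clusters separated
by ~8%, 5'-anchored short fragments (325 bp), sprinkled ambiguity codes,
and injected misidentifications (metadata relabelled to a congener while
the sequence is left untouched).

Genealogy is a star radiation at every level (family ancestor -> genus ->
species -> optional cryptic cluster -> specimen).  Branch depths are chosen
so that each configured depth equals the *expected pairwise* K2P distance
of the corresponding comparison:

    intraspecific pair           ~ intra_depth
    congeneric interspecific     ~ inter_depth        (non-cryptic species)
    cryptic clusters, same species ~ split_depth
    same family, different genus ~ between_genus_depth

i.e. a branch from a parent level at expected pairwise distance ``D`` uses
depth ``(D - intra_depth) / 2`` above the two specimen branches of
``intra_depth / 2`` each.  Sequences evolve under a per-site continuous-time
K2P substitution process with transition/transversion rate ratio ``kappa``;
ancestors are drawn codon-wise from non-stop codons of the invertebrate
mitochondrial code and children containing an in-frame stop are redrawn, so
emitted full-length sequences always pass translation QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._encoding import decode, encode
from .seq_io_qc import (
    SpecimenRecord,
    is_provisional_label,
    write_barcode_fasta,
    write_specimen_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedLibrary",
    "evolve_sequence",
    "simulate_reference_library",
    "plant_diagnostics",
    "choose_plantable_sites",
]

# stop codons under the invertebrate mitochondrial code (table 5)
_STOP_CODONS = {"TAA", "TAG"}
_STOP_CODES = {tuple(encode(c)) for c in _STOP_CODONS}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic library generator (distances in subst/site)."""

    seed: int = 0
    n_genera: int = 5
    species_per_genus: int = 4
    specimens_per_species: int | tuple[int, int] = 10
    seq_length: int = 658
    kappa: float = 3.0
    intra_depth: float = 0.02
    inter_depth: float = 0.12
    between_genus_depth: float = 0.25
    genera_per_family: int = 2
    cryptic_fraction: float = 0.20
    split_depth: float = 0.08
    fragment_fraction: float = 0.10
    fragment_length: int = 325
    ambiguity_rate: float = 0.001
    misid_count: int = 5
    provisional_fraction: float = 0.20

    def validate(self) -> None:
        if self.n_genera < 1 or self.species_per_genus < 1:
            raise ValueError("need at least one genus and one species per genus")
        lo, hi = self.specimen_range
        if lo < 1 or hi < lo:
            raise ValueError("specimens_per_species must be >= 1")
        if self.seq_length < 3:
            raise ValueError("seq_length must cover at least one codon")
        for name in ("intra_depth", "inter_depth", "split_depth", "between_genus_depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cryptic_fraction", "fragment_fraction", "provisional_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.intra_depth <= self.split_depth <= self.inter_depth:
            raise ValueError("expected intra_depth <= split_depth <= inter_depth")

    @property
    def specimen_range(self) -> tuple[int, int]:
        if isinstance(self.specimens_per_species, int):
            return (self.specimens_per_species, self.specimens_per_species)
        return self.specimens_per_species

    @property
    def n_species(self) -> int:
        return self.n_genera * self.species_per_genus


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated library."""

    species_of: dict[str, str] = field(default_factory=dict)  # true species
    cluster_of: dict[str, int] = field(default_factory=dict)  # cluster index within species
    cryptic_species: set[str] = field(default_factory=set)
    clusters_per_species: dict[str, int] = field(default_factory=dict)
    misidentified: dict[str, tuple[str, str]] = field(default_factory=dict)  # id -> (true, assigned)
    fragment_ids: set[str] = field(default_factory=set)
    ambiguous_ids: set[str] = field(default_factory=set)
    planted_diagnostics: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for sid in sorted(self.species_of):
            true_sp = self.species_of[sid]
            assigned = self.misidentified.get(sid, (true_sp, true_sp))[1]
            rows.append(
                {
                    "specimen_id": sid,
                    "true_species": true_sp,
                    "assigned_species": assigned,
                    "cluster": self.cluster_of.get(sid, 0),
                    "is_misidentified": sid in self.misidentified,
                    "is_fragment": sid in self.fragment_ids,
                    "has_ambiguity": sid in self.ambiguous_ids,
                }
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedLibrary:
    sequences: list[tuple[str, str]]  # (specimen_id, bases)
    records: list[SpecimenRecord]
    truth: SyntheticTruth
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "library.fasta",
            "specimens": outdir / "specimens.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_barcode_fasta(paths["fasta"], self.sequences)
        write_specimen_table(paths["specimens"], self.records)
        self.truth.write_tsv(paths["truth"])
        return paths


# ---------------------------------------------------------------------------
# K2P substitution process


def _k2p_site_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after time t.

    Rates are normalised so the expected number of substitutions per site
    over time t is exactly t: alpha + 2*beta = 1 with alpha/beta = kappa.
    """
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv


def _evolve_codes(
    parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    if t < 0:
        raise ValueError("branch length t must be >= 0")
    if t == 0:
        return parent.copy()
    p_same, p_ts, p_tv = _k2p_site_probs(t, kappa)
    u = rng.random(parent.shape[0])
    child = parent.copy()
    concrete = parent < 4
    ts_mask = concrete & (u >= p_same) & (u < p_same + p_ts)
    tv1_mask = concrete & (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv)
    tv2_mask = concrete & (u >= p_same + p_ts + p_tv)
    child[ts_mask] ^= 2  # A<->G, C<->T
    child[tv1_mask] ^= 1
    child[tv2_mask] ^= 3
    return child


def evolve_sequence(parent: str, t: float, kappa: float, rng: np.random.Generator) -> str:
    """Evolve a nucleotide string for ``t`` expected substitutions/site.

    Each site follows an independent continuous-time K2P process with
    transition/transversion rate ratio ``kappa``.  Ambiguous sites are
    carried through unchanged.
    """
    parent_codes = encode(parent.upper())
    child = _evolve_codes(parent_codes, t, kappa, rng)
    out = np.array(list(parent.upper()), dtype="U1")
    concrete = parent_codes < 4
    out[concrete] = np.array(list(decode(child[concrete])), dtype="U1")
    return "".join(out)


def _has_frame0_stop(codes: np.ndarray) -> bool:
    n_codons = codes.shape[0] // 3
    codons = codes[: n_codons * 3].reshape(n_codons, 3)
    for stop in _STOP_CODES:
        if np.any(np.all(codons == np.array(stop), axis=1)):
            return True
    return False


def _evolve_stop_free(
    parent: np.ndarray, t: float, kappa: float, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """Evolve and redraw until the child has no in-frame stop codon."""
    for _ in range(max_tries):
        child = _evolve_codes(parent, t, kappa, rng)
        if not _has_frame0_stop(child):
            return child
    raise RuntimeError("could not draw a stop-free sequence; branch too long?")


def _random_stop_free_ancestor(length: int, rng: np.random.Generator) -> np.ndarray:
    n_codons, rem = divmod(length, 3)
    codons = []
    while len(codons) < n_codons:
        cand = tuple(rng.integers(0, 4, size=3))
        if cand not in _STOP_CODES:
            codons.append(cand)
    flat = np.array(codons, dtype=np.uint8).reshape(-1)
    tail = rng.integers(0, 4, size=rem).astype(np.uint8)
    return np.concatenate([flat, tail])


# ---------------------------------------------------------------------------
# Library generation

_STATES = ("AB", "BC", "SK", "MB", "ON", "QC", "NB", "NY", "PA", "CO", "MT", "OR")


def _alpha_suffix(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ... (keeps genus names digit-free)."""
    out = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


def simulate_reference_library(config: SimulationConfig) -> SimulatedLibrary:
    """Generate a barcode library plus its ground truth.

    The same seed always yields byte-identical FASTA/TSV output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    t_specimen = config.intra_depth / 2.0
    t_cluster = max(0.0, (config.split_depth - config.intra_depth) / 2.0)
    t_species = max(0.0, (config.inter_depth - config.intra_depth) / 2.0)
    t_genus = max(0.0, (config.between_genus_depth - config.inter_depth) / 2.0)

    n_species = config.n_species
    n_cryptic = int(math.floor(config.cryptic_fraction * n_species))
    cryptic_idx = set(
        rng.choice(n_species, size=n_cryptic, replace=False).tolist()
    )
    n_provisional = int(math.floor(config.provisional_fraction * n_species))
    provisional_idx = set(
        rng.choice(n_species, size=n_provisional, replace=False).tolist()
    )

    truth = SyntheticTruth()
    sequences: list[tuple[str, str]] = []
    records: list[SpecimenRecord] = []
    genus_of_species: dict[str, str] = {}
    species_by_genus: dict[str, list[str]] = {}

    lo, hi = config.specimen_range
    spec_counter = 0
    species_index = 0
    family_ancestors: dict[int, np.ndarray] = {}

    for g in range(config.n_genera):
        fam_idx = g // config.genera_per_family
        family = f"Family{fam_idx + 1:02d}"
        genus = f"Genus{_alpha_suffix(g)}"
        if fam_idx not in family_ancestors:
            family_ancestors[fam_idx] = _random_stop_free_ancestor(config.seq_length, rng)
        genus_anc = _evolve_stop_free(family_ancestors[fam_idx], t_genus, config.kappa, rng)
        species_by_genus[genus] = []

        for s in range(config.species_per_genus):
            if species_index in provisional_idx:
                label = f"{genus} sp.SIM{s + 1}"
            else:
                label = f"{genus} species{s + 1:02d}"
            genus_of_species[label] = genus
            species_by_genus[genus].append(label)
            species_anc = _evolve_stop_free(genus_anc, t_species, config.kappa, rng)

            is_cryptic = species_index in cryptic_idx
            if is_cryptic:
                n_clusters = int(rng.integers(2, 4))
                cluster_anc = [
                    _evolve_stop_free(species_anc, t_cluster, config.kappa, rng)
                    for _ in range(n_clusters)
                ]
                truth.cryptic_species.add(label)
            else:
                n_clusters = 1
                cluster_anc = [species_anc]
            truth.clusters_per_species[label] = n_clusters

            n_specimens = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            for k in range(n_specimens):
                cluster = k % n_clusters  # round-robin: clusters never singletons
                codes = _evolve_stop_free(
                    cluster_anc[cluster], t_specimen, config.kappa, rng
                )
                spec_counter += 1
                sid = f"SIM{spec_counter:04d}"
                sequences.append((sid, decode(codes)))
                truth.species_of[sid] = label
                truth.cluster_of[sid] = cluster
                lat = round(float(rng.uniform(25.0, 60.0)), 3)
                lon = round(float(rng.uniform(-130.0, -60.0)), 3)
                records.append(
                    SpecimenRecord(
                        specimen_id=sid,
                        family=family,
                        genus=genus,
                        species_label=label,
                        is_provisional=is_provisional_label(label),
                        id_confidence="expert",
                        life_stage=("larva", "imago", "subimago")[int(rng.integers(0, 3))],
                        country="Canada" if lat > 49 else "United States",
                        state_province=_STATES[int(rng.integers(0, len(_STATES)))],
                        latitude=lat,
                        longitude=lon,
                    )
                )
            species_index += 1

    # 5' fragments
    n_frag = int(math.floor(config.fragment_fraction * len(sequences)))
    frag_idx = rng.choice(len(sequences), size=n_frag, replace=False)
    for i in sorted(frag_idx.tolist()):
        sid, bases = sequences[i]
        sequences[i] = (sid, bases[: config.fragment_length])
        truth.fragment_ids.add(sid)

    # ambiguity codes (N) at a small per-site rate
    if config.ambiguity_rate > 0:
        for i, (sid, bases) in enumerate(sequences):
            mask = rng.random(len(bases)) < config.ambiguity_rate
            if mask.any():
                arr = np.array(list(bases), dtype="U1")
                arr[mask] = "N"
                sequences[i] = (sid, "".join(arr))
                truth.ambiguous_ids.add(sid)

    # misidentifications: relabel metadata to a random other congener
    eligible = [
        i
        for i, r in enumerate(records)
        if len(species_by_genus[r.genus]) > 1
    ]
    if config.misid_count > len(eligible):
        raise ValueError("misid_count exceeds the number of eligible specimens")
    misid_rows = rng.choice(len(eligible), size=config.misid_count, replace=False)
    for row in sorted(misid_rows.tolist()):
        i = eligible[row]
        r = records[i]
        others = [s for s in species_by_genus[r.genus] if s != r.species_label]
        wrong = others[int(rng.integers(0, len(others)))]
        truth.misidentified[r.specimen_id] = (r.species_label, wrong)
        records[i] = SpecimenRecord(
            specimen_id=r.specimen_id,
            family=r.family,
            genus=r.genus,
            species_label=wrong,
            is_provisional=is_provisional_label(wrong),
            id_confidence=r.id_confidence,
            life_stage=r.life_stage,
            country=r.country,
            state_province=r.state_province,
            latitude=r.latitude,
            longitude=r.longitude,
        )

    return SimulatedLibrary(sequences=sequences, records=records, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Diagnostic planting


def plant_diagnostics(
    sequences: Sequence[tuple[str, str]],
    species_of: Mapping[str, str],
    plants: Mapping[str, Mapping[int, str]],
) -> list[tuple[str, str]]:
    """Force fixed states at given 1-based positions for target species.

    ``plants`` maps species -> {position: state}.  Every member of the
    species is set to the state at each position (when the position lies
    within its sequence).  Raises if a plant would create an in-frame stop
    codon.
    """
    out = []
    for sid, bases in sequences:
        species = species_of.get(sid)
        if species in plants:
            arr = np.array(list(bases), dtype="U1")
            for pos, state in sorted(plants[species].items()):
                if not 1 <= pos <= len(bases):
                    continue
                if state not in "ACGT":
                    raise ValueError(f"bad diagnostic state {state!r}")
                arr[pos - 1] = state
            new = "".join(arr)
            if _has_frame0_stop(encode(new)):
                raise ValueError(
                    f"planting {dict(plants[species])} in {sid} creates a stop codon"
                )
            out.append((sid, new))
        else:
            out.append((sid, bases))
    return out


def choose_plantable_sites(
    sequences: Sequence[tuple[str, str]],
    species_of: Mapping[str, str],
    species: str,
    k: int,
    rng: np.random.Generator,
) -> dict[int, str]:
    """Pick ``k`` (position, state) plants guaranteed diagnostic for ``species``.

    A candidate state must be absent from every *other* species at the
    position, and planting it into every member of ``species`` must not
    create an in-frame stop codon.
    """
    member_seqs = [b for sid, b in sequences if species_of.get(sid) == species]
    other_seqs = [b for sid, b in sequences if species_of.get(sid) != species]
    if not member_seqs:
        raise ValueError(f"no sequences for species {species!r}")
    max_pos = min(len(b) for b in member_seqs)
    plants: dict[int, str] = {}
    positions = rng.permutation(max_pos) + 1
    for pos in positions:
        if len(plants) >= k:
            break
        used = {b[pos - 1] for b in other_seqs if len(b) >= pos}
        free = [s for s in "ACGT" if s not in used]
        if not free:
            continue
        state = free[int(rng.integers(0, len(free)))]
        try:
            plant_diagnostics(
                [(f"m{i}", b) for i, b in enumerate(member_seqs)],
                {f"m{i}": species for i in range(len(member_seqs))},
                {species: {int(pos): state}},
            )
        except ValueError:
            continue
        plants[int(pos)] = state
    if len(plants) < k:
        raise ValueError(f"could only find {len(plants)} plantable sites of {k}")
    return plants
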
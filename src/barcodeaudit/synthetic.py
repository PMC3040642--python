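"""Synthetic barcode libraries with known ground truth.

Generates a library with the statistical structure the audit assumes in a
well-curated regional moth library: genera of a few species each, strong
separation between species (cross-genus ~13% K2P, congeneric ~10%), very
low within-species variation (~0.2%), plus controllable injected
anomalies — exact barcode sharing between two species, deep intraspecific
splits (two haplotype clusters several percent apart, tagged with
different geographic regions), species pairs planted at chosen low
divergences, and short (<500 bp) records.

Sequences evolve under the Kimura 2-parameter substitution model on a
star phylogeny: a root ancestor, genus ancestors at one star, species
centroids at a star within each genus, and specimens evolved
independently from their centroid.  K2P distances are additive in
expectation along paths, so pairwise targets translate directly into
branch lengths.  No indels, no rate variation across sites, no
coalescent realism — the point is distance-level structure with an exact
truth table, not genealogies.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .seqio import BarcodeRecord, Library

__all__ = ["SimConfig", "SimTruth", "evolve", "simulate_library"]

_BASES = "ACGT"
_REGIONS = ("Alps", "Danube", "Franken", "BayWald")
# deep-split clusters get distinct regions, emulating the geographic
# structure often seen behind deep intraspecific divergence
_SPLIT_REGIONS = ("Alps", "BayWald")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the simulated library.

    Distance targets are K2P proportions.  Defaults mirror a typical
    European geometrid library: 13% between genera, 10% between
    congeners, 0.2% within species, deep splits at 4.4%.  ``kappa`` is
    the transition/transversion rate ratio (4.0 is typical for insect
    mitochondrial COI).
    """

    n_species: int = 300
    specimens_per_species: int = 3
    species_per_genus: int = 3
    seq_length: int = 658
    kappa: float = 4.0
    target_interspecific_d: float = 0.13
    target_congeneric_d: float = 0.10
    target_intraspecific_d: float = 0.002
    n_sharing_pairs: int = 1
    n_deep_splits: int = 20
    deep_split_d: float = 0.044
    low_divergence_pairs: tuple[float, ...] = ()
    n_short_records: int = 0
    short_length: int = 450
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100")
        if self.specimens_per_species < 1 or self.species_per_genus < 1:
            raise ValueError("counts must be >= 1")
        for name in (
            "target_interspecific_d",
            "target_congeneric_d",
            "target_intraspecific_d",
            "deep_split_d",
        ):
            v = getattr(self, name)
            if not 0 < v < 0.75:
                raise ValueError(f"{name}={v} outside (0, 0.75)")
        if self.target_congeneric_d > self.target_interspecific_d:
            raise ValueError("congeneric target cannot exceed cross-genus target")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def n_genera(self) -> int:
        return math.ceil(self.n_species / self.species_per_genus)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated library.

    ``centroids`` maps species -> its (first) centroid haplotype;
    ``sharing_pairs`` lists (donor, recipient, shared_specimen_id);
    ``deep_splits`` maps species -> (cluster separation, ids in cluster 1,
    ids in cluster 2); ``low_divergence`` lists planted species pairs with
    their target distance; ``short_records`` lists truncated specimen ids.
    """

    genus_of: dict[str, str]
    centroids: dict[str, str]
    sharing_pairs: tuple[tuple[str, str, str], ...]
    deep_splits: dict[str, tuple[float, tuple[str, ...], tuple[str, ...]]]
    low_divergence: tuple[tuple[str, str, float], ...]
    short_records: tuple[str, ...]


def _k2p_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """Per-site transition/transversion substitution probabilities P(d), Q(d).

    With transition rate a and (each-type) transversion rate b, kappa=a/b
    and total distance d=(a+2b)t:

        Q = 1/2 - 1/2 exp(-4bt)
        P = 1/4 - 1/2 exp(-2(a+b)t) + 1/4 exp(-4bt)

    so the expected estimated K2P distance between a sequence and its
    mutated copy equals d.
    """
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-2.0 * (at + bt))
    e2 = math.exp(-4.0 * bt)
    q = 0.5 - 0.5 * e2
    p = 0.25 - 0.5 * e1 + 0.25 * e2
    return p, q


def evolve(seq: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Mutate a sequence to an expected K2P distance ``d`` from the input.

    Each site changes independently: with probability P(d) to its
    transition partner, with probability Q(d)/2 to each transversion
    partner.  ``d = 0`` returns the input unchanged.
    """
    if not 0 <= d <= 0.75:
        raise ValueError(f"target distance {d} outside [0, 0.75]")
    if d == 0:
        return seq
    code = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = np.full(len(code), 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        enc[code == ord(b)] = {"A": 0, "C": 1, "G": 2, "T": 3}[b]
    if np.any(enc == 255):
        raise ValueError("evolve requires a pure A/C/G/T sequence")
    p, q = _k2p_site_probs(d, kappa)
    u = rng.random(len(enc))
    pick = rng.integers(0, 2, size=len(enc)).astype(np.uint8)
    out = enc.copy()
    ts = u < p
    out[ts] ^= 2  # A<->G (0<->2), C<->T (1<->3)
    tv = (~ts) & (u < p + q)
    # transversion partners of x are the two bases of opposite parity
    out[tv] = (enc[tv] ^ 1) ^ (2 * pick[tv])
    return "".join(_BASES[i] for i in out)


def mutate_fixed_counts(
    seq: str, d: float, kappa: float, rng: np.random.Generator
) -> str:
    """Apply exactly the substitution counts implied by target distance ``d``.

    Rounds the expected transition/transversion counts P(d)*L and Q(d)*L
    to integers and applies them at distinct random sites, so the
    estimated K2P distance of (seq, result) equals the target up to the
    1/L rounding granularity — used when a pair must sit *at* a nominal
    divergence (e.g. planting a species pair inside a screening window)
    rather than scattered around it.
    """
    if not 0 <= d <= 0.75:
        raise ValueError(f"target distance {d} outside [0, 0.75]")
    if d == 0:
        return seq
    p, q = _k2p_site_probs(d, kappa)
    length = len(seq)
    nts, ntv = round(p * length), round(q * length)
    sites = rng.choice(length, size=nts + ntv, replace=False)
    out = list(seq)
    partner_ts = {"A": "G", "G": "A", "C": "T", "T": "C"}
    partner_tv = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    for s in sites[:nts]:
        out[s] = partner_ts[out[s]]
    for s in sites[nts:]:
        out[s] = partner_tv[out[s]][rng.integers(0, 2)]
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_library(cfg: SimConfig) -> tuple[Library, SimTruth]:
    """Simulate a barcode library and its ground-truth table.

    Branch lengths realise the targets: species sit ``congeneric/2`` from
    their genus ancestor and genus ancestors ``(cross-genus −
    congeneric)/2`` from the root, so congeneric centroids are ~10%
    apart and cross-genus centroids ~13%; specimens evolve
    ``intraspecific/2`` from their centroid.

    Anomalies: each sharing pair is two congeners given the *same*
    centroid, with one recipient specimen an exact copy of a donor
    specimen (distance exactly 0) — so sharing does not mechanically
    create a deep split.  Each deep-split species gets a second centroid
    ``deep_split_d`` away, specimens split between the clusters (the
    smaller cluster holds floor(k/2), so k=3 gives a single-outlier
    case), clusters tagged with different regions.  Planted
    low-divergence pairs are congeners whose second centroid carries
    exactly the substitution counts implied by the given distance, so the
    pair sits at its nominal divergence rather than scattered around it.

    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_sp, k = cfg.n_species, cfg.specimens_per_species

    # --- choose anomaly species (disjoint sets, deterministic in seed)
    n_pair_slots = cfg.n_sharing_pairs + len(cfg.low_divergence_pairs)
    needed = 2 * n_pair_slots + cfg.n_deep_splits
    congeneric_pairs_available = sum(
        min(cfg.species_per_genus, n_sp - g * cfg.species_per_genus) // 2
        for g in range(cfg.n_genera)
    )
    if n_pair_slots > congeneric_pairs_available or needed > n_sp:
        raise ValueError("more planted anomalies than species can host")

    species_names = [
        f"Genus{(i // cfg.species_per_genus) + 1:03d} species{i + 1:03d}"
        for i in range(n_sp)
    ]
    genus_of = {s: s.split()[0] for s in species_names}

    # congeneric pairs for sharing / low-divergence planting: take species
    # (2g, 2g+1) within successive genera
    pair_slots: list[tuple[int, int]] = []
    g = 0
    while len(pair_slots) < n_pair_slots:
        base = g * cfg.species_per_genus
        if base + 1 < min(base + cfg.species_per_genus, n_sp):
            pair_slots.append((base, base + 1))
        g += 1
    paired = {i for ab in pair_slots for i in ab}
    deep_idx = [i for i in range(n_sp) if i not in paired][: cfg.n_deep_splits]

    sharing_slots = pair_slots[: cfg.n_sharing_pairs]
    lowdiv_slots = pair_slots[cfg.n_sharing_pairs :]

    # --- centroids
    root = _random_seq(cfg.seq_length, rng)
    g_branch = (cfg.target_interspecific_d - cfg.target_congeneric_d) / 2.0
    s_branch = cfg.target_congeneric_d / 2.0
    genus_anc = [
        evolve(root, g_branch, cfg.kappa, rng) if g_branch > 0 else root
        for _ in range(cfg.n_genera)
    ]
    centroids: list[str] = [
        evolve(genus_anc[i // cfg.species_per_genus], s_branch, cfg.kappa, rng)
        for i in range(n_sp)
    ]
    for a, b in sharing_slots:
        centroids[b] = centroids[a]
    lowdiv_truth = []
    for (a, b), d_target in zip(lowdiv_slots, cfg.low_divergence_pairs):
        centroids[b] = mutate_fixed_counts(centroids[a], d_target, cfg.kappa, rng)
        lowdiv_truth.append((species_names[a], species_names[b], d_target))

    second_centroid = {
        i: evolve(centroids[i], cfg.deep_split_d, cfg.kappa, rng) for i in deep_idx
    }

    # --- specimens
    spec_branch = cfg.target_intraspecific_d / 2.0
    records: list[BarcodeRecord] = []
    deep_truth: dict[str, tuple[float, tuple[str, ...], tuple[str, ...]]] = {}
    counter = 0
    for i, sp in enumerate(species_names):
        ids = []
        for j in range(k):
            counter += 1
            ids.append(f"SIM{counter:05d}")
        if i in second_centroid:
            n2 = k // 2  # smaller cluster; k=3 -> single outlier
            members1, members2 = ids[: k - n2], ids[k - n2 :]
            for sid in members1:
                seq = evolve(centroids[i], spec_branch, cfg.kappa, rng)
                records.append(BarcodeRecord(sid, sp, seq, _SPLIT_REGIONS[0]))
            for sid in members2:
                seq = evolve(second_centroid[i], spec_branch, cfg.kappa, rng)
                records.append(BarcodeRecord(sid, sp, seq, _SPLIT_REGIONS[1]))
            deep_truth[sp] = (cfg.deep_split_d, tuple(members1), tuple(members2))
        else:
            for sid in ids:
                seq = evolve(centroids[i], spec_branch, cfg.kappa, rng)
                region = _REGIONS[rng.integers(0, len(_REGIONS))]
                records.append(BarcodeRecord(sid, sp, seq, region))

    # --- exact sharing: recipient's first specimen copies donor's first
    by_species: dict[str, list[int]] = {}
    for idx, r in enumerate(records):
        by_species.setdefault(r.species, []).append(idx)
    sharing_truth = []
    for a, b in sharing_slots:
        donor = records[by_species[species_names[a]][0]]
        ri = by_species[species_names[b]][0]
        rec = records[ri]
        records[ri] = BarcodeRecord(rec.specimen_id, rec.species, donor.sequence, rec.region)
        sharing_truth.append((species_names[a], species_names[b], rec.specimen_id))

    # --- short records (truncate tail; padding happens in Library)
    short_ids = []
    if cfg.n_short_records:
        if cfg.n_short_records > len(records):
            raise ValueError("more short records than specimens")
        anomalous = {sid for _, _, sid in sharing_truth}
        for t in deep_truth.values():
            anomalous.update(t[1] + t[2])
        eligible = [i for i, r in enumerate(records) if r.specimen_id not in anomalous]
        chosen = rng.choice(len(eligible), size=cfg.n_short_records, replace=False)
        for c in sorted(chosen):
            i = eligible[int(c)]
            r = records[i]
            records[i] = BarcodeRecord(
                r.specimen_id, r.species, r.sequence[: cfg.short_length], r.region
            )
            short_ids.append(r.specimen_id)

    truth = SimTruth(
        genus_of=genus_of,
        centroids=dict(zip(species_names, centroids)),
        sharing_pairs=tuple(sharing_truth),
        deep_splits=deep_truth,
        low_divergence=tuple(lowdiv_truth),
        short_records=tuple(short_ids),
    )
    return Library(tuple(records), alignment_length=cfg.seq_length), truth


def truth_rows(truth: SimTruth) -> tuple[list[str], list[list[str]]]:
    """Flatten a SimTruth into TSV rows (kind, species1, species2, detail)."""
    cols = ["kind", "species1", "species2", "detail"]
    rows: list[list[str]] = []
    for sp, genus in sorted(truth.genus_of.items()):
        rows.append(["species", sp, "", genus])
    for a, b, sid in truth.sharing_pairs:
        rows.append(["sharing", a, b, sid])
    for sp, (depth, c1, c2) in sorted(truth.deep_splits.items()):
        rows.append(["deep_split", sp, "", f"{depth};{','.join(c1)};{','.join(c2)}"])
    for a, b, d in truth.low_divergence:
        rows.append(["low_divergence", a, b, f"{d}"])
    for sid in truth.short_records:
        rows.append(["short_record", "", "", sid])
    return cols, rows
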
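"""Barcode-gap audit of a reference library.

Implements the species-level screens used when auditing a regional
barcode library against its Linnaean taxonomy:

* **MPD** — maximum intraspecific pairwise distance, the measure of
  within-species variation (singletons have none);
* **NN** — each species' nearest heterospecific neighbour, taken as the
  minimum over specimen pairs;
* **barcode sharing** — heterospecific specimen pairs at exactly zero
  distance;
* **low-divergence pairs** — species pairs whose minimum distance falls
  in a screening window, (1%, 4%] by default;
* **deep intraspecific splits** — species whose MPD exceeds a threshold
  (strictly > 2% by default), with their single-linkage haplotype
  subclusters;
* **global strata** — mean/SE/n of all interspecific, congeneric
  interspecific, and intraspecific comparisons, the latter also after
  excluding deep-split species (whose possible cryptic diversity inflates
  apparent intraspecific variation).

All distances are proportions internally; rendering to percent happens
only in :mod:`barcodeaudit.report`.  SEs are sample SD / sqrt(n) over
pairwise comparisons — descriptive only, since comparisons sharing a
specimen are not independent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .k2p import DistanceMatrix

__all__ = [
    "SpeciesAudit",
    "AuditReport",
    "StratumStats",
    "DeepSplit",
    "SharingPair",
    "Histogram",
    "max_intraspecific",
    "nearest_neighbor",
    "global_stats",
    "detect_sharing",
    "low_divergence_pairs",
    "detect_deep_splits",
    "resolution_rate",
    "histogram",
    "run_audit",
]

DEEP_SPLIT_THRESHOLD = 0.02
LOW_DIVERGENCE_WINDOW = (0.01, 0.04)
HISTOGRAM_BIN_WIDTH = 0.005


# ---------------------------------------------------------------------------
# species-level reductions of the specimen matrix


def _species_blocks(m: DistanceMatrix) -> dict[str, np.ndarray]:
    """Map species -> specimen indices, species sorted lexicographically."""
    blocks: dict[str, list[int]] = {}
    for i, sp in enumerate(m.species):
        blocks.setdefault(sp, []).append(i)
    return {sp: np.asarray(blocks[sp]) for sp in sorted(blocks)}


def _species_min_matrix(m: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    """Minimum defined specimen distance per species pair (NaN if none)."""
    blocks = _species_blocks(m)
    names = list(blocks)
    s = len(names)
    out = np.full((s, s), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN blocks
        for a in range(s):
            ia = blocks[names[a]]
            rows = m.d[ia]
            for b in range(a + 1, s):
                v = np.nanmin(rows[:, blocks[names[b]]])
                out[a, b] = out[b, a] = v
    np.fill_diagonal(out, 0.0)
    return names, out


def max_intraspecific(m: DistanceMatrix) -> dict[str, float]:
    """MPD per species with >=2 specimens; singletons are omitted.

    Species whose conspecific pairs are all missing are omitted with a
    warning.
    """
    out: dict[str, float] = {}
    for sp, idx in _species_blocks(m).items():
        if len(idx) < 2:
            continue
        block = m.d[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        if np.all(np.isnan(block)):
            warnings.warn(
                f"species {sp!r}: all conspecific pairs missing; MPD undefined"
            )
            continue
        out[sp] = float(np.nanmax(block))
    return out


def nearest_neighbor(m: DistanceMatrix) -> dict[str, tuple[str, float]]:
    """Nearest heterospecific neighbour per species.

    The NN distance is the minimum defined distance over all
    heterospecific specimen pairs; ties go to the lexicographically
    smallest species name.  Species with no defined heterospecific pair
    are omitted with a warning.
    """
    names, smin = _species_min_matrix(m)
    if len(names) < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 species")
    out: dict[str, tuple[str, float]] = {}
    for a, sp in enumerate(names):
        row = smin[a].copy()
        row[a] = np.nan
        if np.all(np.isnan(row)):
            warnings.warn(f"species {sp!r}: no defined heterospecific pair")
            continue
        b = int(np.nanargmin(row))  # first occurrence = lexicographic winner
        out[sp] = (names[b], float(row[b]))
    return out


# ---------------------------------------------------------------------------
# global strata


@dataclass(frozen=True)
class StratumStats:
    """Mean/SE/n over the pairwise comparisons of one stratum."""

    mean: float
    se: float
    n: int
    se_defined: bool = True

    @classmethod
    def of(cls, values: np.ndarray) -> "StratumStats":
        values = values[~np.isnan(values)]
        n = len(values)
        if n == 0:
            return cls(float("nan"), float("nan"), 0, False)
        if n == 1:
            return cls(float(values[0]), 0.0, 1, False)
        return cls(
            float(values.mean()), float(values.std(ddof=1) / np.sqrt(n)), n, True
        )


def _genus(species: str) -> str:
    return species.split()[0]


def global_stats(
    m: DistanceMatrix, deep_split_species: Iterable[str] = ()
) -> dict[str, StratumStats]:
    """Mean/SE/n for the four divergence strata.

    Strata over unordered defined specimen pairs: ``interspecific`` (all
    heterospecific), ``congeneric`` (heterospecific, same genus),
    ``intraspecific`` (conspecific, singletons contribute nothing), and
    ``intraspecific_excl_deep`` which removes every specimen of the given
    deep-split species first.
    """
    excl = set(deep_split_species)
    sp = np.asarray(m.species)
    genus = np.asarray([_genus(s) for s in m.species])
    iu, ju = np.triu_indices(len(m), 1)
    vals = m.d[iu, ju]
    same_sp = sp[iu] == sp[ju]
    same_genus = genus[iu] == genus[ju]
    keep = ~np.isin(sp[iu], list(excl)) & ~np.isin(sp[ju], list(excl))
    return {
        "interspecific": StratumStats.of(vals[~same_sp]),
        "congeneric": StratumStats.of(vals[~same_sp & same_genus]),
        "intraspecific": StratumStats.of(vals[same_sp]),
        "intraspecific_excl_deep": StratumStats.of(vals[same_sp & keep]),
    }


# ---------------------------------------------------------------------------
# anomaly screens


@dataclass(frozen=True)
class SharingPair:
    """Two species with specimen pairs at exactly zero distance."""

    species1: str
    species2: str
    specimen_pairs: tuple[tuple[str, str], ...]

    @property
    def n_pairs(self) -> int:
        return len(self.specimen_pairs)

    @property
    def regular(self) -> bool:
        """More than one identical specimen pair (not a one-off)."""
        return self.n_pairs > 1


def detect_sharing(m: DistanceMatrix) -> list[SharingPair]:
    """Heterospecific specimen pairs at distance exactly 0, by species pair."""
    sp = np.asarray(m.species)
    iu, ju = np.triu_indices(len(m), 1)
    hit = (m.d[iu, ju] == 0) & (sp[iu] != sp[ju])
    agg: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, j in zip(iu[hit], ju[hit]):
        key = tuple(sorted((m.species[i], m.species[j])))
        pair = tuple(sorted((m.ids[i], m.ids[j])))
        agg.setdefault(key, []).append(pair)
    return [
        SharingPair(k[0], k[1], tuple(sorted(v))) for k, v in sorted(agg.items())
    ]


def low_divergence_pairs(
    m: DistanceMatrix,
    lower: float = LOW_DIVERGENCE_WINDOW[0],
    upper: float = LOW_DIVERGENCE_WINDOW[1],
) -> list[tuple[str, str, float]]:
    """Species pairs whose minimum distance lies in ``(lower, upper]``.

    Bounds are proportions.  Unordered pairs, sorted ascending by
    distance (ties by name), each listed once.
    """
    if not 0 <= lower < upper:
        raise ValueError("need 0 <= lower < upper")
    names, smin = _species_min_matrix(m)
    out = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            v = smin[a, b]
            if not np.isnan(v) and lower < v <= upper:
                out.append((names[a], names[b], float(v)))
    return sorted(out, key=lambda r: (r[2], r[0], r[1]))


@dataclass(frozen=True)
class DeepSplit:
    """A species whose conspecific haplotypes fall in clusters >threshold apart."""

    species: str
    mpd: float
    subclusters: tuple[tuple[str, ...], ...]  # specimen ids per cluster

    @property
    def n_subclusters(self) -> int:
        return len(self.subclusters)

    @property
    def singleton_outlier(self) -> bool:
        """True when the split is carried by a single outlier specimen."""
        return self.n_subclusters == 2 and min(map(len, self.subclusters)) == 1


def detect_deep_splits(
    m: DistanceMatrix, threshold: float = DEEP_SPLIT_THRESHOLD
) -> dict[str, DeepSplit]:
    """Species with MPD strictly above ``threshold`` and their subclusters.

    Subclusters are connected components of single-linkage among
    conspecific specimens, linking pairs at defined distance <=
    threshold — the weakest clustering assumption consistent with
    'lineages more than threshold apart'.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    mpds = max_intraspecific(m)
    blocks = _species_blocks(m)
    out: dict[str, DeepSplit] = {}
    for sp, mpd in mpds.items():
        if not mpd > threshold:
            continue
        idx = blocks[sp]
        sub = m.d[np.ix_(idx, idx)]
        adj = np.nan_to_num(sub, nan=np.inf) <= threshold
        n_comp, labels = connected_components(csr_matrix(adj), directed=False)
        clusters = tuple(
            tuple(m.ids[idx[k]] for k in np.flatnonzero(labels == c))
            for c in range(n_comp)
        )
        clusters = tuple(sorted(clusters, key=lambda c: (-len(c), c)))
        out[sp] = DeepSplit(sp, mpd, clusters)
    return out


def resolution_rate(m: DistanceMatrix) -> tuple[int, float]:
    """Fraction of species diagnosable by their barcodes.

    A species is diagnosable iff its minimum defined heterospecific
    distance is strictly positive (no specimen shares a haplotype across
    the species boundary).  Species without a computable NN are excluded
    from the denominator.
    """
    nn = nearest_neighbor(m)
    if not nn:
        raise ValueError("no species with computable nearest neighbour")
    n_diag = sum(1 for _, dist in nn.values() if dist > 0)
    return n_diag, n_diag / len(nn)


# ---------------------------------------------------------------------------
# histograms


@dataclass(frozen=True)
class Histogram:
    """Counts per half-open bin [k*w, (k+1)*w) of fixed width w."""

    bin_width: float
    counts: tuple[int, ...]

    @property
    def total(self) -> int:
        return sum(self.counts)

    def edges(self) -> list[tuple[float, float]]:
        w = self.bin_width
        return [(k * w, (k + 1) * w) for k in range(len(self.counts))]


def histogram(values: Sequence[float], bin_width: float = HISTOGRAM_BIN_WIDTH) -> Histogram:
    """Bin non-negative values into half-open classes of ``bin_width``."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        return Histogram(bin_width, ())
    if np.any(np.isnan(vals)) or np.any(vals < 0):
        raise ValueError("histogram values must be finite and >= 0")
    idx = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(idx)
    return Histogram(bin_width, tuple(int(c) for c in counts))


# ---------------------------------------------------------------------------
# assembled report


@dataclass(frozen=True)
class SpeciesAudit:
    """Per-species audit line: variation, nearest neighbour, and flags."""

    species: str
    n_specimens: int
    mpd: float | None
    nn_species: str | None
    nn_distance: float | None
    n_subclusters: int
    flags: frozenset[str]


@dataclass(frozen=True)
class AuditReport:
    """Everything the audit computes, ready for rendering."""

    audits: tuple[SpeciesAudit, ...]
    stats: Mapping[str, StratumStats]
    low_divergence: tuple[tuple[str, str, float], ...]
    sharing: tuple[SharingPair, ...]
    deep_splits: Mapping[str, DeepSplit]
    nn_hist: Histogram
    mpd_hist: Histogram
    n_diagnosable: int
    resolution: float
    params: Mapping[str, float]
    counts: Mapping[str, int]


def run_audit(
    m: DistanceMatrix,
    deep_split_threshold: float = DEEP_SPLIT_THRESHOLD,
    low_div_window: tuple[float, float] = LOW_DIVERGENCE_WINDOW,
    bin_width: float = HISTOGRAM_BIN_WIDTH,
) -> AuditReport:
    """Full audit of a distance matrix.

    The NN histogram covers species with a computable NN, excluding
    deep-split species (their status is in question); the MPD histogram
    excludes singletons.  Flags per species: SINGLETON, SHARING
    (NN distance exactly 0), LOW_DIVERGENCE (NN in the screening window),
    DEEP_SPLIT (MPD strictly above threshold).
    """
    lower, upper = low_div_window
    mpds = max_intraspecific(m)
    nn = nearest_neighbor(m)
    splits = detect_deep_splits(m, deep_split_threshold)
    sharing = detect_sharing(m)
    stats = global_stats(m, deep_split_species=splits)
    lowdiv = low_divergence_pairs(m, lower, upper)
    n_diag, frac = resolution_rate(m)

    blocks = _species_blocks(m)
    audits = []
    for sp in blocks:
        n_spec = len(blocks[sp])
        mpd = mpds.get(sp)
        nn_sp, nn_d = nn.get(sp, (None, None))
        flags = set()
        if n_spec == 1:
            flags.add("SINGLETON")
        if nn_d is not None and nn_d == 0:
            flags.add("SHARING")
        if nn_d is not None and lower < nn_d <= upper:
            flags.add("LOW_DIVERGENCE")
        if sp in splits:
            flags.add("DEEP_SPLIT")
        audits.append(
            SpeciesAudit(
                species=sp,
                n_specimens=n_spec,
                mpd=mpd,
                nn_species=nn_sp,
                nn_distance=nn_d,
                n_subclusters=splits[sp].n_subclusters if sp in splits else 1,
                flags=frozenset(flags),
            )
        )

    nn_vals = [d for sp, (_, d) in nn.items() if sp not in splits]
    mpd_vals = list(mpds.values())
    iu, ju = np.triu_indices(len(m), 1)
    counts = {
        "n_specimens": len(m),
        "n_species": len(blocks),
        "n_defined_pairs": int(m.defined[iu, ju].sum()),
        "n_low_overlap_pairs": m.n_low_overlap,
        "n_saturated_pairs": m.n_saturated,
        "n_deep_split_species": len(splits),
        "n_deep_split_singleton_outlier": sum(
            1 for s in splits.values() if s.singleton_outlier
        ),
        "n_sharing_species_pairs": len(sharing),
    }
    return AuditReport(
        audits=tuple(audits),
        stats=stats,
        low_divergence=tuple(lowdiv),
        sharing=tuple(sharing),
        deep_splits=splits,
        nn_hist=histogram(nn_vals, bin_width),
        mpd_hist=histogram(mpd_vals, bin_width),
        n_diagnosable=n_diag,
        resolution=frac,
        params={
            "min_overlap": m.min_overlap,
            "deep_split_threshold": deep_split_threshold,
            "low_div_lower": lower,
            "low_div_upper": upper,
            "bin_width": bin_width,
        },
        counts=counts,
    )
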
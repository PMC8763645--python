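"""Pseudocolor barcode codebooks and error-correcting spot decoding.

seqFISH identifies each mRNA species by a temporal barcode: in each of four
coding rounds of hybridization the molecule lights up in one of 12
pseudocolors (a pseudocolor is a (fluorophore channel, sub-round) pair), and
a fifth parity round makes the 5-tuple error correctable.  Decoding groups
per-round fluorescent dots that colocalize in space into barcodes and maps
them back to genes, repairing a single missing or corrupted round.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Codebook",
    "build_codebook",
    "decode_spots",
    "parity_symbol",
    "pseudocolor_channel_map",
]

#: Columns a per-round spot table must provide.
ROUND_SPOT_COLUMNS = (
    "spot_id",
    "round",
    "pseudocolor",
    "x",
    "y",
    "z_slice",
    "fov",
    "embryo",
)


def parity_symbol(prefix: tuple[int, ...], n_pseudocolors: int = 12) -> int:
    """Parity pseudocolor for a coding-round prefix.

    The parity round carries ``((sum(prefix) - len(prefix)) mod P) + 1`` so
    that any four of the five rounds determine the fifth uniquely: the full
    codeword set has minimum pairwise Hamming distance 2.
    """
    return (sum(prefix) - len(prefix)) % n_pseudocolors + 1


def pseudocolor_channel_map(n_pseudocolors: int = 12, n_channels: int = 3) -> dict[int, tuple[int, int]]:
    """Map each pseudocolor to its (fluorophore channel, sub-round) pair.

    Pseudocolors are spread evenly across the fluorescent channels:
    channel ``((p-1) mod C) + 1``, sub-round ``ceil(p / C)``.
    """
    return {
        p: ((p - 1) % n_channels + 1, (p - 1) // n_channels + 1)
        for p in range(1, n_pseudocolors + 1)
    }


@dataclass(frozen=True)
class Codebook:
    """Gene -> 5-round pseudocolor codewords with a parity round.

    The first ``n_coding_rounds`` symbols are the information-carrying
    prefix; the final symbol is the parity.  Prefixes are pairwise distinct,
    so full codewords are at Hamming distance >= 2 from each other.
    """

    genes: tuple[str, ...]
    codewords: dict[str, tuple[int, ...]]
    n_pseudocolors: int = 12
    n_coding_rounds: int = 4
    n_parity_rounds: int = 1
    channel_map: dict[int, tuple[int, int]] = field(default_factory=pseudocolor_channel_map)

    @property
    def n_rounds(self) -> int:
        return self.n_coding_rounds + self.n_parity_rounds

    @property
    def capacity(self) -> int:
        """Number of distinct codeword prefixes available."""
        return self.n_pseudocolors ** self.n_coding_rounds

    def validate(self) -> None:
        prefixes = {cw[: self.n_coding_rounds] for cw in self.codewords.values()}
        if len(prefixes) != len(self.codewords):
            raise ValueError("codeword prefixes are not pairwise distinct")
        for gene, cw in self.codewords.items():
            if len(cw) != self.n_rounds:
                raise ValueError(f"codeword for {gene!r} has wrong length")
            if not all(1 <= p <= self.n_pseudocolors for p in cw):
                raise ValueError(f"codeword for {gene!r} has out-of-range pseudocolor")
            expected = parity_symbol(cw[: self.n_coding_rounds], self.n_pseudocolors)
            if cw[-1] != expected:
                raise ValueError(f"codeword for {gene!r} has inconsistent parity symbol")

    def lookup(self) -> dict[tuple[int, ...], str]:
        """Inverse map: full codeword -> gene."""
        return {cw: g for g, cw in self.codewords.items()}

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{i + 1}": [self.codewords[g][i] for g in self.genes] for i in range(self.n_rounds)}
        return pd.DataFrame({"gene": list(self.genes), **cols})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_pseudocolors: int = 12) -> "Codebook":
        pc_cols = sorted(c for c in df.columns if c.startswith("pc"))
        codewords = {
            row["gene"]: tuple(int(row[c]) for c in pc_cols) for _, row in df.iterrows()
        }
        cb = cls(
            genes=tuple(df["gene"]),
            codewords=codewords,
            n_pseudocolors=n_pseudocolors,
            n_coding_rounds=len(pc_cols) - 1,
        )
        cb.validate()
        return cb


def enumerate_prefixes(n_pseudocolors: int, n_coding_rounds: int):
    """Exhaustively enumerate the coding-round codeword space."""
    return itertools.product(range(1, n_pseudocolors + 1), repeat=n_coding_rounds)


def build_codebook(
    gene_ids,
    n_pseudocolors: int = 12,
    n_coding_rounds: int = 4,
    seed: int = 0,
) -> Codebook:
    """Assign each gene a random codeword prefix plus its parity symbol.

    Prefixes are sampled without replacement from the full
    ``n_pseudocolors ** n_coding_rounds`` space.
    """
    gene_ids = list(gene_ids)
    capacity = n_pseudocolors**n_coding_rounds
    if len(gene_ids) > capacity:
        raise ValueError(
            f"{len(gene_ids)} genes exceed the codeword capacity "
            f"{n_pseudocolors}^{n_coding_rounds} = {capacity}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(capacity, size=len(gene_ids), replace=False)
    codewords = {}
    for gene, i in zip(gene_ids, idx):
        digits = []
        rem = int(i)
        for _ in range(n_coding_rounds):
            digits.append(rem % n_pseudocolors + 1)
            rem //= n_pseudocolors
        prefix = tuple(digits)
        codewords[gene] = prefix + (parity_symbol(prefix, n_pseudocolors),)
    cb = Codebook(
        genes=tuple(gene_ids),
        codewords=codewords,
        n_pseudocolors=n_pseudocolors,
        n_coding_rounds=n_coding_rounds,
        channel_map=pseudocolor_channel_map(n_pseudocolors),
    )
    cb.validate()
    return cb


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def _match_codeword(observed: dict[int, int], codebook: Codebook):
    """Match observed {round: pseudocolor} to a gene.

    Returns (gene, corrected) or (None, False).  With all rounds observed we
    first try the exact codeword, then a unique Hamming-distance-1 repair.
    With one round missing, at most one codeword can agree on the observed
    rounds (minimum distance 2), so the match, if any, is unique.
    """
    lut = codebook.lookup()
    n_rounds = codebook.n_rounds
    if len(observed) == n_rounds:
        full = tuple(observed[r] for r in range(1, n_rounds + 1))
        gene = lut.get(full)
        if gene is not None:
            return gene, False
        candidates = [
            g
            for cw, g in lut.items()
            if sum(a != b for a, b in zip(cw, full)) == 1
        ]
        if len(candidates) == 1:
            return candidates[0], True
        return None, False
    if len(observed) == n_rounds - 1:
        candidates = [
            g
            for cw, g in lut.items()
            if all(cw[r - 1] == pc for r, pc in observed.items())
        ]
        if len(candidates) == 1:
            return candidates[0], True
    return None, False


class _FovDots:
    """Per-round dot arrays plus KD-trees for one (embryo, z_slice, fov)."""

    def __init__(self, df: pd.DataFrame, n_rounds: int):
        self.rounds = {}
        for r in range(1, n_rounds + 1):
            sub = df[df["round"] == r].sort_values("spot_id")
            self.rounds[r] = {
                "spot_id": sub["spot_id"].to_numpy(),
                "xy": sub[["x", "y"]].to_numpy(dtype=float),
                "pc": sub["pseudocolor"].to_numpy(dtype=int),
            }
        self.trees = {
            r: cKDTree(d["xy"]) if len(d["spot_id"]) else None
            for r, d in self.rounds.items()
        }

    def nearest(self, r: int, xy: np.ndarray, radius: float):
        """Index of the nearest dot in round ``r`` within ``radius``.

        Distance ties are broken toward the smallest spot_id so decoding is
        deterministic on exactly coincident dots.
        """
        tree = self.trees[r]
        if tree is None:
            return None
        cand = tree.query_ball_point(xy, radius)
        if not cand:
            return None
        d = self.rounds[r]
        dist = np.linalg.norm(d["xy"][cand] - xy, axis=1)
        best = np.min(dist)
        ties = [c for c, dd in zip(cand, dist) if dd <= best + 1e-12]
        return min(ties, key=lambda c: d["spot_id"][c])


def _decode_fov(df: pd.DataFrame, codebook: Codebook, radius: float, min_seed_support: int):
    dots = _FovDots(df, codebook.n_rounds)
    n_rounds = codebook.n_rounds
    calls = []  # (gene, corrected, residual, centroid, dots_used, seed_round)
    for seed_round in range(1, codebook.n_coding_rounds + 1):
        seed = dots.rounds[seed_round]
        for i in range(len(seed["spot_id"])):
            xy = seed["xy"][i]
            used = {seed_round: i}
            for r in range(1, n_rounds + 1):
                if r == seed_round:
                    continue
                j = dots.nearest(r, xy, radius)
                if j is None:
                    continue
                # symmetric nearest neighbors: the seed must also be the
                # partner's nearest dot back in the seed round
                back = dots.nearest(seed_round, dots.rounds[r]["xy"][j], radius)
                if back == i:
                    used[r] = j
            if len(used) < n_rounds - 1:
                continue
            observed = {r: int(dots.rounds[r]["pc"][j]) for r, j in used.items()}
            gene, corrected = _match_codeword(observed, codebook)
            if gene is None:
                continue
            pts = np.array([dots.rounds[r]["xy"][j] for r, j in used.items()])
            centroid = pts.mean(axis=0)
            residual = float(np.sqrt(((pts - centroid) ** 2).sum(axis=1).mean()))
            dot_ids = {r: int(dots.rounds[r]["spot_id"][j]) for r, j in used.items()}
            calls.append(
                {
                    "gene": gene,
                    "corrected": corrected,
                    "residual": residual,
                    "centroid": centroid,
                    "dots": dot_ids,
                    "seed_round": seed_round,
                    "n_rounds_used": len(used),
                }
            )

    # Merge calls across seedings: same gene, centroids within the search
    # radius.  A physical spot is retained only when called identically from
    # at least `min_seed_support` of the coding-round seedings.
    calls.sort(key=lambda c: (c["residual"], c["gene"], c["centroid"][0], c["centroid"][1]))
    clusters = []
    for call in calls:
        for cl in clusters:
            if cl["gene"] == call["gene"] and np.linalg.norm(cl["centroid"] - call["centroid"]) < radius:
                if call["seed_round"] not in cl["seed_rounds"]:
                    cl["seed_rounds"].add(call["seed_round"])
                break
        else:
            clusters.append(
                {
                    "gene": call["gene"],
                    "centroid": call["centroid"],
                    "residual": call["residual"],
                    "dots": call["dots"],
                    "corrected": call["corrected"],
                    "n_rounds_used": call["n_rounds_used"],
                    "seed_rounds": {call["seed_round"]},
                }
            )

    retained = [c for c in clusters if len(c["seed_rounds"]) >= min_seed_support]
    # Greedy conflict resolution: accept in order of increasing residual;
    # each physical dot may support at most one decoded spot.
    retained.sort(key=lambda c: (c["residual"], c["gene"], c["centroid"][0], c["centroid"][1]))
    consumed = set()
    out = []
    for c in retained:
        keys = {(r, sid) for r, sid in c["dots"].items()}
        if keys & consumed:
            continue
        consumed |= keys
        out.append(c)
    return out


def decode_spots(
    rounds: pd.DataFrame,
    codebook: Codebook,
    radius: float = 2.45,
    min_seed_support: int = 3,
) -> pd.DataFrame:
    """Decode per-round dot tables into gene-assigned mRNA spots.

    For every dot of each coding round taken as a seed, symmetric nearest
    neighbors within ``radius`` in the other rounds form a candidate barcode;
    the pseudocolor sequence is matched to the codebook with single-round
    error correction.  Calls must agree across at least ``min_seed_support``
    of the four seedings, and each dot supports at most one decoded spot
    (conflicts resolved greedily by increasing positional residual).

    Parameters
    ----------
    rounds
        Table with columns ``spot_id, round, pseudocolor, x, y, z_slice,
        fov, embryo``; decoding is 2D, per (embryo, z_slice, fov).
    radius
        Search radius in pixels (default 2.45).

    Returns
    -------
    DataFrame with one row per decoded spot: gene, centroid x/y, provenance,
    ``n_rounds_used``, ``n_seed_support`` and the ``corrected`` flag.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    missing = set(ROUND_SPOT_COLUMNS) - set(rounds.columns)
    if missing:
        raise ValueError(f"round spot table is missing columns: {sorted(missing)}")
    empty = pd.DataFrame(
        columns=[
            "gene",
            "x",
            "y",
            "z_slice",
            "fov",
            "embryo",
            "n_rounds_used",
            "n_seed_support",
            "corrected",
        ]
    )
    if len(rounds) == 0:
        return empty
    bad_pc = ~rounds["pseudocolor"].between(1, codebook.n_pseudocolors)
    if bad_pc.any():
        raise ValueError(
            "pseudocolors outside the codebook's range "
            f"1..{codebook.n_pseudocolors} in the round table"
        )
    records = []
    for (embryo, z_slice, fov), df in rounds.groupby(["embryo", "z_slice", "fov"], sort=True):
        for c in _decode_fov(df, codebook, radius, min_seed_support):
            records.append(
                {
                    "gene": c["gene"],
                    "x": c["centroid"][0],
                    "y": c["centroid"][1],
                    "z_slice": z_slice,
                    "fov": fov,
                    "embryo": embryo,
                    "n_rounds_used": c["n_rounds_used"],
                    "n_seed_support": len(c["seed_rounds"]),
                    "corrected": c["corrected"],
                }
            )
    if not records:
        return empty
    return pd.DataFrame.from_records(records)
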
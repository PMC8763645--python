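"""Gene panel selection under expression-load constraints, and probe filters.

A multiplexed FISH panel must separate every cell type from every other
while keeping the total fluorescent signal per cell low enough that single
molecules remain optically resolvable.  Selection ranks genes per cell type
by a pairwise marker test (Welch t-test against a minimum absolute log fold
change), takes the top-ranked genes per type per developmental stage,
unions across stages, and then removes high-load genes until per-type and
per-cell expression budgets are met.

Probe filtering scores every 30-nt window of a transcript for GC content,
homopolymer runs and exact 15-mer off-target matches (an exact-match k-mer
index standing in for a transcriptome BLAST screen), keeps a non-overlapping
subset, and iteratively removes probes with too many 15-mer hits against
the pooled probe set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PanelConstraints",
    "ProbeRules",
    "PanelSelection",
    "select_panel",
    "candidate_windows",
    "filter_probes",
    "design_probe_library",
]


@dataclass(frozen=True)
class PanelConstraints:
    lfc_test_threshold: float = 0.5  # log2; the pairwise test's null bound
    top_n_per_type: int = 5
    max_upper_quartile: float = 20.0  # normalized counts
    max_type_load: float = 300.0  # summed mean normalized counts per type
    target_max_transcripts_per_cell: float = 200.0
    min_cells_per_type: int = 10

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class ProbeRules:
    probe_length: int = 30
    gc_min: float = 0.45
    gc_max: float = 0.65
    max_homopolymer: int = 4  # longest allowed run of one base
    offtarget_match_len: int = 15
    max_internal_offtarget_hits: int = 7
    min_probes_barcoded: int = 28
    min_probes_smfish: int = 17

    def __post_init__(self):
        if not 0 < self.gc_min < self.gc_max < 1:
            raise ValueError("require 0 < gc_min < gc_max < 1")


@dataclass
class PanelSelection:
    genes: list
    per_stage: dict = field(default_factory=dict)
    dropped_upper_quartile: list = field(default_factory=list)
    dropped_load: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)


def _pairwise_marker_table(lognorm: np.ndarray, types: np.ndarray, genes, lfc_threshold: float):
    """Per type, each gene's best rank over pairwise marker comparisons.

    For types (t, u) and each gene, a Welch t-test of the null
    |log2 FC| <= lfc_threshold: t = (|d| - thr) / se, one-sided.  Genes are
    ranked per comparison by p-value (ties by |d| descending, then gene id);
    a gene's "top" value for type t is its best rank over all comparisons.
    """
    uniq = sorted(np.unique(types).astype(str).tolist())
    stats_by_type = {}
    for t in uniq:
        Xt = lognorm[types.astype(str) == t]
        stats_by_type[t] = (Xt.mean(axis=0), Xt.var(axis=0, ddof=1), len(Xt))
    top = pd.DataFrame(np.inf, index=list(genes), columns=uniq)
    for t in uniq:
        mt, vt, nt = stats_by_type[t]
        for u in uniq:
            if u == t:
                continue
            mu, vu, nu = stats_by_type[u]
            d = mt - mu
            se = np.sqrt(vt / nt + vu / nu)
            se[se == 0] = np.inf
            tt = (np.abs(d) - lfc_threshold) / se
            df = (vt / nt + vu / nu) ** 2 / (
                (vt / nt) ** 2 / max(nt - 1, 1) + (vu / nu) ** 2 / max(nu - 1, 1)
            )
            df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
            p = stats.t.sf(tt, df)
            order = pd.DataFrame({"p": p, "absd": -np.abs(d), "gene": list(genes)})
            order = order.sort_values(["p", "absd", "gene"], kind="stable")
            ranks = pd.Series(np.arange(1, len(order) + 1), index=order["gene"])
            top[t] = np.minimum(top[t].to_numpy(), ranks.reindex(list(genes)).to_numpy())
    return top


def select_panel(reference, constraints: PanelConstraints = PanelConstraints(), stages=None) -> PanelSelection:
    """Select a spatial gene panel from a labeled reference atlas.

    ``reference`` is an AnnData with ``layers['lognorm']`` (log2, unit-mean
    size factors, pseudocount 1) and ``obs['cell_type']`` /
    ``obs['stage']``.  Expected transcript counts are recovered from the
    log values as ``2**x - 1``.
    """
    obs = reference.obs
    genes = list(reference.var_names)
    lognorm = np.asarray(reference.layers["lognorm"], dtype=float)
    if stages is None:
        stages = sorted(obs["stage"].astype(str).unique()) if "stage" in obs else ["all"]

    per_stage = {}
    for stage in stages:
        mask = (
            obs["stage"].astype(str) == str(stage)
            if "stage" in obs
            else np.ones(len(obs), dtype=bool)
        )
        X = lognorm[np.asarray(mask)]
        types = obs.loc[mask, "cell_type"].to_numpy()
        t_ids, t_counts = np.unique(types.astype(str), return_counts=True)
        keep_types = t_ids[t_counts >= constraints.min_cells_per_type]
        if len(keep_types) < 2:
            raise ValueError(
                f"stage {stage!r} has fewer than 2 cell types with at least "
                f"{constraints.min_cells_per_type} cells"
            )
        sel = np.isin(types.astype(str), keep_types)
        top = _pairwise_marker_table(X[sel], types[sel], genes, constraints.lfc_test_threshold)
        chosen = set()
        for t in top.columns:
            chosen |= set(top.index[top[t] <= constraints.top_n_per_type])
        per_stage[stage] = sorted(chosen)

    panel = sorted(set().union(*per_stage.values())) if per_stage else []

    # expression-load filters on the whole reference
    norm_counts = 2.0**lognorm - 1.0
    types_all = obs["cell_type"].astype(str).to_numpy()
    t_ids = np.unique(types_all)
    gi = {g: i for i, g in enumerate(genes)}

    uq = {
        t: np.percentile(norm_counts[types_all == t], 75, axis=0) for t in t_ids
    }
    dropped_uq = [
        g for g in panel if any(uq[t][gi[g]] > constraints.max_upper_quartile for t in t_ids)
    ]
    panel = [g for g in panel if g not in set(dropped_uq)]

    mean_by_type = {t: norm_counts[types_all == t].mean(axis=0) for t in t_ids}
    dropped_load = []
    while panel:
        cols = [gi[g] for g in panel]
        loads = {t: float(mean_by_type[t][cols].sum()) for t in t_ids}
        per_cell_total = float(norm_counts[:, cols].sum(axis=1).mean())
        if max(loads.values()) < constraints.max_type_load and per_cell_total <= constraints.target_max_transcripts_per_cell:
            break
        # drop the gene with the largest maximum per-type load; ties by id
        peak = max(max(mean_by_type[t][gi[g]] for t in t_ids) for g in panel)
        worst = min(
            g for g in panel if max(mean_by_type[t][gi[g]] for t in t_ids) == peak
        )
        panel.remove(worst)
        dropped_load.append(worst)

    return PanelSelection(
        genes=panel,
        per_stage=per_stage,
        dropped_upper_quartile=sorted(dropped_uq),
        dropped_load=dropped_load,
        diagnostics={
            "n_candidates": sum(len(v) for v in per_stage.values()),
        },
    )


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

_VALID = set("ACGT")


def _kmers(seq: str, k: int):
    return (seq[i : i + k] for i in range(len(seq) - k + 1))


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def candidate_windows(sequence: str, rules: ProbeRules, offtarget_kmers: set) -> pd.DataFrame:
    """Score every probe-length window of a transcript against the rules."""
    if set(sequence) - _VALID:
        raise ValueError("sequence contains non-ACGT characters")
    L = rules.probe_length
    rows = []
    for start in range(len(sequence) - L + 1):
        w = sequence[start : start + L]
        gc = (w.count("G") + w.count("C")) / L
        rows.append(
            {
                "start": start,
                "seq": w,
                "gc": gc,
                "gc_ok": rules.gc_min <= gc <= rules.gc_max,
                "run_ok": _max_run(w) <= rules.max_homopolymer,
                "offtarget_ok": not any(
                    km in offtarget_kmers for km in _kmers(w, rules.offtarget_match_len)
                ),
            }
        )
    df = pd.DataFrame(rows, columns=["start", "seq", "gc", "gc_ok", "run_ok", "offtarget_ok"])
    df["accepted"] = df[["gc_ok", "run_ok", "offtarget_ok"]].all(axis=1) if len(df) else []
    return df


def _offtarget_index(transcripts, k: int) -> set:
    km = set()
    for seq in transcripts:
        km.update(_kmers(seq, k))
    return km


def _greedy_nonoverlapping(df: pd.DataFrame, L: int) -> pd.DataFrame:
    chosen = []
    next_free = -1
    for _, row in df.sort_values("start").iterrows():
        if row["start"] > next_free:
            chosen.append(row)
            next_free = row["start"] + L - 1
    return pd.DataFrame(chosen)


def _internal_hits(probes: list[str], k: int) -> np.ndarray:
    """15-mer hit counts of each probe against all *other* probes."""
    counts: dict[str, int] = {}
    per_probe = []
    for p in probes:
        kms = list(_kmers(p, k))
        per_probe.append(kms)
        for km in kms:
            counts[km] = counts.get(km, 0) + 1
    hits = np.zeros(len(probes), dtype=int)
    for i, kms in enumerate(per_probe):
        own = {}
        for km in kms:
            own[km] = own.get(km, 0) + 1
        hits[i] = sum((counts[km] - n_own) * n_own for km, n_own in own.items())
    return hits


def filter_probes(transcript_sequence: str, rules: ProbeRules = ProbeRules(), other_transcripts=()):
    """Accepted, non-overlapping probes for one transcript.

    Every probe-length window is scored; windows pass on GC content,
    homopolymer runs and the absence of any ``offtarget_match_len``-mer
    shared with the other transcripts.  Accepted windows are greedily
    selected left-to-right to be non-overlapping, then probes with more
    than ``max_internal_offtarget_hits`` k-mer hits against the pooled
    accepted set are iteratively removed (worst first).
    """
    if len(transcript_sequence) < rules.probe_length:
        raise ValueError("sequence shorter than the probe length")
    idx = _offtarget_index(other_transcripts, rules.offtarget_match_len)
    windows = candidate_windows(transcript_sequence, rules, idx)
    accepted = windows[windows["accepted"]]
    if not len(accepted):
        return []
    chosen = _greedy_nonoverlapping(accepted, rules.probe_length)
    probes = list(chosen["seq"])
    while probes:
        hits = _internal_hits(probes, rules.offtarget_match_len)
        worst = int(np.argmax(hits))
        if hits[worst] <= rules.max_internal_offtarget_hits:
            break
        probes.pop(worst)
    return probes


def design_probe_library(transcripts: dict[str, str], rules: ProbeRules = ProbeRules(), smfish_genes=()):
    """Probe sets for a panel of transcripts, with gene-level minimums.

    Each gene's windows are screened against every *other* transcript; the
    internal off-target pass pools accepted probes across all genes.  Genes
    failing their minimum probe count (barcoded vs smFISH) are dropped.
    Returns a table (gene, probe, start-free sequence only).
    """
    per_gene = {}
    for gene, seq in transcripts.items():
        others = [s for g, s in transcripts.items() if g != gene]
        idx = _offtarget_index(others, rules.offtarget_match_len)
        windows = candidate_windows(seq, rules, idx)
        accepted = windows[windows["accepted"]]
        per_gene[gene] = list(_greedy_nonoverlapping(accepted, rules.probe_length)["seq"]) if len(accepted) else []

    # pooled internal off-target screen
    flat = [(g, p) for g, probes in per_gene.items() for p in probes]
    while flat:
        hits = _internal_hits([p for _, p in flat], rules.offtarget_match_len)
        worst = int(np.argmax(hits))
        if hits[worst] <= rules.max_internal_offtarget_hits:
            break
        flat.pop(worst)

    rebuilt: dict[str, list] = {g: [] for g in transcripts}
    for g, p in flat:
        rebuilt[g].append(p)
    rows = []
    for g, probes in rebuilt.items():
        minimum = rules.min_probes_smfish if g in set(smfish_genes) else rules.min_probes_barcoded
        if len(probes) < minimum:
            continue
        rows.extend({"gene": g, "probe": p} for p in probes)
    return pd.DataFrame(rows, columns=["gene", "probe"])
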
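"""Leave-one-gene-out transcriptome imputation and its scoring scheme.

For each panel gene, the spatial cells are re-mapped onto the reference
atlas using the remaining panel genes (an "intermediate mapping"), and the
withheld gene's expression is imputed as the mean over each cell's 25
nearest reference neighbors.  Per-gene quality is summarized by

* performance score - Pearson r between imputed and measured spatial values;
* prediction score - the same leave-one-out exercise run entirely inside
  the reference (one sequencing batch held out as query), scored by a
  weighted Pearson r with weights proportional to how often each reference
  cell appeared among spatial neighbors;
* normalized score - performance / prediction, the headline per-gene metric.

The final imputation pools neighbor sets over all intermediate mappings and
takes an occurrence-weighted mean over the full reference transcriptome, so
imputed profiles sit on the reference log-count scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .integrate import integrate_datasets, transfer_labels

__all__ = [
    "IntermediateMapping",
    "ImputationScore",
    "make_intermediate_mappings",
    "impute_gene",
    "score_imputation",
    "occurrence_weights",
    "evaluate_normalized_performance",
    "final_impute",
]


@dataclass
class IntermediateMapping:
    """Neighbor sets obtained with one panel gene withheld."""

    withheld_gene: str
    neighbor_indices: np.ndarray  # spatial cells x k, indices into the reference
    features: tuple  # genes actually used


@dataclass
class ImputationScore:
    value: float
    ok: bool
    reason: str = ""


def _neighbors(query_lognorm, ref_lognorm, query_batches, ref_batches, k, n_components, sigma):
    qc, rc = integrate_datasets(
        query_lognorm, ref_lognorm, query_batches, ref_batches,
        n_components=n_components, sigma=sigma,
    )
    dummy = np.zeros(len(rc))
    return transfer_labels(qc, rc, dummy, k=k).neighbor_indices


def make_intermediate_mappings(
    spatial_lognorm: pd.DataFrame,
    ref_lognorm: pd.DataFrame,
    spatial_batches,
    ref_batches,
    panel=None,
    excluded=(),
    k: int = 25,
    n_components: int = 50,
    sigma: float | None = None,
) -> list[IntermediateMapping]:
    """One intermediate mapping per non-excluded panel gene.

    For each gene g the full integration pipeline is rerun on the panel
    minus {g} (and minus the excluded genes, e.g. the sex-specific gene),
    and each spatial cell's ``k`` nearest reference neighbors are recorded.
    """
    if panel is None:
        panel = list(spatial_lognorm.columns)
    usable = [g for g in panel if g not in set(excluded)]
    if len(usable) < 3:
        raise ValueError(f"panel has {len(usable)} usable genes; at least 3 required")
    mappings = []
    for g in usable:
        feats = [x for x in usable if x != g]
        idx = _neighbors(
            spatial_lognorm[feats].to_numpy(),
            ref_lognorm[feats].to_numpy(),
            spatial_batches,
            ref_batches,
            k,
            min(n_components, len(feats)),
            sigma,
        )
        mappings.append(IntermediateMapping(g, idx, tuple(feats)))
    return mappings


def impute_gene(mapping: IntermediateMapping, ref_expression: np.ndarray) -> np.ndarray:
    """Unweighted mean of the withheld gene over each cell's neighbors."""
    ref_expression = np.asarray(ref_expression, dtype=float)
    if mapping.neighbor_indices.max() >= len(ref_expression):
        raise ValueError("neighbor id missing from the reference expression vector")
    return ref_expression[mapping.neighbor_indices].mean(axis=1)


def score_imputation(imputed, measured, mode: str = "plain", weights=None) -> ImputationScore:
    """Pearson (or weighted Pearson) correlation between imputed and measured.

    Weighted mode uses weighted covariance over the square root of the
    weighted variances.  Zero variance in either vector is flagged rather
    than propagated as NaN.
    """
    x = np.asarray(imputed, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape:
        raise ValueError("imputed and measured must have equal length")
    if mode == "plain":
        w = np.ones_like(x)
    elif mode == "weighted":
        if weights is None:
            raise ValueError("weighted mode requires weights")
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative and not all zero")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    wn = w / w.sum()
    mx = wn @ x
    my = wn @ y
    vx = wn @ (x - mx) ** 2
    vy = wn @ (y - my) ** 2
    if vx == 0 or vy == 0:
        which = "imputed" if vx == 0 else "measured"
        return ImputationScore(float("nan"), False, f"zero variance in {which} values")
    cov = wn @ ((x - mx) * (y - my))
    return ImputationScore(float(cov / np.sqrt(vx * vy)), True)


def occurrence_weights(mappings, n_ref: int) -> np.ndarray:
    """How often each reference cell appears among neighbors, over all genes."""
    w = np.zeros(n_ref)
    for m in mappings:
        idx, counts = np.unique(m.neighbor_indices, return_counts=True)
        w[idx] += counts
    return w


def evaluate_normalized_performance(
    spatial_lognorm: pd.DataFrame,
    ref_lognorm: pd.DataFrame,
    spatial_batches,
    ref_batches,
    panel=None,
    excluded=(),
    k: int = 25,
    n_components: int = 50,
    sigma: float | None = None,
    holdout_batch=None,
) -> pd.DataFrame:
    """Per-gene performance, prediction and normalized imputation scores.

    The prediction score holds one reference batch out as the query set
    (default: the largest), restricts the reference to panel genes and to
    cells that appeared among spatial neighbors, and repeats the
    leave-one-gene-out imputation inside the reference; it is scored by a
    weighted Pearson r with the spatial-mapping occurrence counts of the
    query cells as weights.

    Returns a table (gene, performance, prediction, normalized, reason).
    """
    ref_batches = np.asarray(ref_batches)
    batch_ids, batch_sizes = np.unique(ref_batches, return_counts=True)
    if len(batch_ids) < 2:
        raise ValueError("prediction score requires a reference with at least 2 batches")
    if panel is None:
        panel = list(spatial_lognorm.columns)
    usable = [g for g in panel if g not in set(excluded)]

    mappings = make_intermediate_mappings(
        spatial_lognorm, ref_lognorm, spatial_batches, ref_batches,
        panel=panel, excluded=excluded, k=k, n_components=n_components, sigma=sigma,
    )
    w_ref = occurrence_weights(mappings, len(ref_lognorm))

    performance = {}
    for m in mappings:
        imput = impute_gene(m, ref_lognorm[m.withheld_gene].to_numpy())
        performance[m.withheld_gene] = score_imputation(
            imput, spatial_lognorm[m.withheld_gene].to_numpy(), mode="plain"
        )

    # held-out-batch self-imputation inside the reference
    if holdout_batch is None:
        holdout_batch = batch_ids[np.argmax(batch_sizes)]
    seen = w_ref > 0
    is_query = (ref_batches == holdout_batch) & seen
    is_train = (ref_batches != holdout_batch) & seen
    query_df = ref_lognorm.loc[is_query, usable]
    train_df = ref_lognorm.loc[is_train, usable]
    qb = ref_batches[is_query]
    tb = ref_batches[is_train]
    w_query = w_ref[is_query]

    prediction = {}
    if is_query.sum() >= 2 and is_train.sum() >= k:
        pred_maps = make_intermediate_mappings(
            query_df, train_df, qb, tb,
            panel=usable, k=k, n_components=n_components, sigma=sigma,
        )
        for m in pred_maps:
            imput = impute_gene(m, train_df[m.withheld_gene].to_numpy())
            prediction[m.withheld_gene] = score_imputation(
                imput, query_df[m.withheld_gene].to_numpy(), mode="weighted", weights=w_query
            )

    rows = []
    for g in usable:
        perf = performance.get(g, ImputationScore(float("nan"), False, "not mapped"))
        pred = prediction.get(g, ImputationScore(float("nan"), False, "prediction unavailable"))
        if perf.ok and pred.ok and pred.value != 0:
            norm = perf.value / pred.value
            reason = ""
        else:
            norm = float("nan")
            reason = perf.reason or pred.reason or "zero prediction score"
        rows.append(
            {
                "gene": g,
                "performance": perf.value,
                "prediction": pred.value,
                "normalized": norm,
                "reason": reason,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out.attrs["occurrence_weights"] = w_ref
    out.attrs["holdout_batch"] = holdout_batch
    return out


def final_impute(mappings, ref_full_lognorm: pd.DataFrame) -> pd.DataFrame:
    """Occurrence-weighted imputation of the full reference transcriptome.

    For each spatial cell, neighbor ids are pooled over every intermediate
    mapping; the weight of a reference cell is the number of times it
    occurred.  Every reference gene's imputed value is the weighted mean of
    its log-normalized reference expression, so the output is on the
    reference log scale.
    """
    if not mappings:
        raise ValueError("no intermediate mappings supplied")
    n_cells = mappings[0].neighbor_indices.shape[0]
    n_ref = len(ref_full_lognorm)
    W = np.zeros((n_cells, n_ref))
    for m in mappings:
        if m.neighbor_indices.shape[0] != n_cells:
            raise ValueError("mappings disagree on the number of spatial cells")
        np.add.at(W, (np.repeat(np.arange(n_cells), m.neighbor_indices.shape[1]),
                      m.neighbor_indices.ravel()), 1.0)
    W /= W.sum(axis=1, keepdims=True)
    vals = W @ ref_full_lognorm.to_numpy(dtype=float)
    return pd.DataFrame(vals, columns=ref_full_lognorm.columns)
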
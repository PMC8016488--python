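"""Imbalance-aware assignment metrics and the in-/out-model confidence analysis.

Accuracy (fraction of correct assignments among all inputs) is biased toward
the largest groups, so macro-averaged precision and recall are reported
alongside: per-group values averaged unweighted over the groups present in the
truth, giving rare groups equal say. "unassigned" counts as incorrect for
accuracy and as a non-prediction for precision; a group that is never
predicted gets precision 0 so the macro average stays well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alphabet_io import UNASSIGNED, ProteinRecord
from .inference import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    ConfidenceHistogram,
    PredictionResult,
    assign,
    confidence_histogram,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    per_group: pd.DataFrame  # columns: group, precision, recall, support


def score(predictions: list[PredictionResult], truth: dict[str, str]) -> MetricsReport:
    """Accuracy plus per-group and macro-averaged precision/recall.

    Every predicted id must carry a truth label. Macro averages run over the
    groups present in the truth (a group only ever predicted, never true,
    contributes to false positives but gets no row of its own).
    """
    missing = [p.sequence_id for p in predictions if p.sequence_id not in truth]
    if missing:
        raise ValueError(f"prediction id(s) without a truth label: {missing[:5]}")
    if not predictions:
        raise ValueError("no predictions to score")
    groups = sorted(set(truth[p.sequence_id] for p in predictions))
    tp = {g: 0 for g in groups}
    fp = {g: 0 for g in groups}
    support = {g: 0 for g in groups}
    correct = 0
    for p in predictions:
        true_g = truth[p.sequence_id]
        support[true_g] += 1
        if p.group == true_g:
            tp[true_g] += 1
            correct += 1
        elif p.group != UNASSIGNED and p.group in tp:
            fp[p.group] += 1
    rows = []
    for g in groups:
        predicted = tp[g] + fp[g]
        precision = tp[g] / predicted if predicted else 0.0
        recall = tp[g] / support[g]
        rows.append((g, precision, recall, support[g]))
    per_group = pd.DataFrame(rows, columns=["group", "precision", "recall", "support"])
    return MetricsReport(
        accuracy=correct / len(predictions),
        macro_precision=float(per_group["precision"].mean()),
        macro_recall=float(per_group["recall"].mean()),
        per_group=per_group,
    )


@dataclass(frozen=True)
class InOutAnalysis:
    """Confidence distributions of in-model vs out-model sequences.

    Out-model sequences belong to groups the model does not know; a good
    classifier is much less confident about them, so the two histograms
    separate and the threshold can sit between them.
    """

    in_histogram: ConfidenceHistogram
    out_histogram: ConfidenceHistogram
    threshold: float
    in_above: int
    in_below: int
    out_above: int
    out_below: int
    in_confidences: np.ndarray
    out_confidences: np.ndarray


def in_out_model_analysis(
    model,
    in_records: list[ProteinRecord],
    out_records: list[ProteinRecord],
    out_groups: dict[str, str] | set[str],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    batch_size: int = 64,
) -> InOutAnalysis:
    """Score both sets and compare their rank-1 confidence distributions.

    ``out_groups`` carries the true groups of the out-model records (a mapping
    id -> group or a set of group ids); they must be disjoint from the model's
    label map, otherwise the analysis would be meaningless.
    """
    from .inference import _resolve_model

    state, label_map = _resolve_model(model)
    out_set = set(out_groups.values()) if isinstance(out_groups, dict) else set(out_groups)
    overlap = out_set & set(label_map.group_ids)
    if overlap:
        raise ValueError(
            f"out-model group(s) {sorted(overlap)[:5]} are present in the model's label map"
        )
    in_results = assign((state, label_map), in_records, threshold=0.0, batch_size=batch_size)
    out_results = assign((state, label_map), out_records, threshold=0.0, batch_size=batch_size)
    in_conf = np.array([r.confidence for r in in_results])
    out_conf = np.array([r.confidence for r in out_results])
    return InOutAnalysis(
        in_histogram=confidence_histogram(in_results),
        out_histogram=confidence_histogram(out_results),
        threshold=threshold,
        in_above=int((in_conf >= threshold).sum()),
        in_below=int((in_conf < threshold).sum()),
        out_above=int((out_conf >= threshold).sum()),
        out_below=int((out_conf < threshold).sum()),
        in_confidences=in_conf,
        out_confidences=out_conf,
    )


def export_embeddings(model) -> pd.DataFrame:
    """The learned amino-acid embedding as a table: one row per residue code.

    The padding row is excluded; values are exactly the embedding weights, so
    the table can feed any dimensionality-reduction or clustering tool.
    """
    from .architecture import load_model
    from .alphabet_io import build_extended_alphabet
    from pathlib import Path

    if isinstance(model, (str, Path)):
        state, _ = load_model(model)
    else:
        state, _ = model
    if "embedding" not in state.params:
        raise ValueError("model has no embedding layer (baseline variant)")
    emb = state.params["embedding"][1:]  # drop the padding row
    alphabet = build_extended_alphabet()
    df = pd.DataFrame(emb, columns=[f"d{j}" for j in range(emb.shape[1])])
    df.insert(0, "symbol", list(alphabet.symbols))
    return df
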
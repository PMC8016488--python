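"""Confidence-thresholded group assignment over arbitrary FASTA input.

The softmax output is read as the network's confidence that a sequence belongs
to each group in the model. A sequence is assigned its rank-1 group only when
that confidence reaches the threshold (default 99%, a strict setting chosen to
keep false assignments of out-model sequences rare); otherwise it is reported
as "unassigned", with the rank-1 probability still attached so results can be
re-thresholded without re-running the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import architecture
from .alphabet_io import (
    UNASSIGNED,
    GroupLabelMap,
    ProteinRecord,
    SequenceTooLongError,
    build_extended_alphabet,
    encode_pseudo_onehot,
    encode_sequence,
    pad_and_batch,
)
from .architecture import ModelState

logger = logging.getLogger(__name__)

DEFAULT_CONFIDENCE_THRESHOLD = 0.99


@dataclass(frozen=True)
class PredictionResult:
    sequence_id: str
    group: str  # a group id, or "unassigned"
    confidence: float  # rank-1 softmax probability


@dataclass(frozen=True)
class ConfidenceHistogram:
    """Counts of rank-1 confidences in 100 bins of width 0.01.

    Bins are half-open [x, x+0.01) except the last, which is closed at 1.0.
    """

    edges: np.ndarray
    counts: np.ndarray


def _resolve_model(model) -> tuple[ModelState, GroupLabelMap]:
    if isinstance(model, (str, Path)):
        return architecture.load_model(model)
    return model  # (state, label_map) pair


def assign(
    model,
    records: list[ProteinRecord],
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
    batch_size: int = 64,
) -> list[PredictionResult]:
    """Assign each record to its rank-1 group if confidence >= threshold.

    ``model`` is an archive path or a (state, label_map) pair. Output order
    follows input order, and results are independent of ``batch_size`` (the
    masked pooling makes logits invariant to padding and batch companions).
    Under the fixed-length baseline, sequences longer than the model's input
    length cannot be scored and are reported unassigned with confidence 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    state, label_map = _resolve_model(model)
    if not records:
        logger.warning("no input sequences; returning an empty result list")
        return []
    alphabet = build_extended_alphabet()
    results: list[PredictionResult] = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        if state.config.variant == "deepnog":
            encoded = [encode_sequence(r, alphabet) for r in chunk]
            inputs = pad_and_batch(encoded, min_length=max(state.config.filter_sizes))
            scorable = list(range(len(chunk)))
        else:
            onehots, scorable = [], []
            for j, r in enumerate(chunk):
                try:
                    onehots.append(encode_pseudo_onehot(r, state.config.fixed_length))
                    scorable.append(j)
                except SequenceTooLongError:
                    pass
            inputs = np.stack(onehots) if onehots else None
        probs = architecture.predict_proba(
            architecture.forward(state, inputs, training=False)
        ) if inputs is not None else np.zeros((0, len(label_map)))
        chunk_results = [
            PredictionResult(r.id, UNASSIGNED, 0.0) for r in chunk
        ]
        top = probs.argmax(axis=1) if probs.size else np.array([], dtype=int)
        for row, j in enumerate(scorable):
            conf = float(probs[row, top[row]])
            group = label_map.group_ids[int(top[row])] if conf >= threshold else UNASSIGNED
            chunk_results[j] = PredictionResult(chunk[j].id, group, conf)
        results.extend(chunk_results)
    return results


def confidence_histogram(results: list[PredictionResult]) -> ConfidenceHistogram:
    """Bin rank-1 confidences into 100 bins of width 0.01 over [0, 1]."""
    if not results:
        raise ValueError("cannot histogram an empty result list")
    edges = np.round(np.linspace(0.0, 1.0, 101), 2)
    counts, _ = np.histogram([r.confidence for r in results], bins=edges)
    return ConfidenceHistogram(edges=edges, counts=counts)
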
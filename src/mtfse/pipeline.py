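"""Glue: segments -> TFSI -> index vectors -> feature matrix."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .indices import INDEX_NAMES, IndexVector, Quantizer, compute_indices
from .preprocess import HRVSegment
from .spectrum import build_tfsi

__all__ = ["segment_indices", "extract_features"]

log = logging.getLogger("mtfse")


def segment_indices(
    segment: HRVSegment, config: PipelineConfig | None = None
) -> IndexVector:
    """Compute the eight MTFSE indices of one segment."""
    if config is None:
        config = PipelineConfig()
    tfsi = build_tfsi(
        segment,
        window_length_s=config.tfsi_window_s,
        hop_s=config.tfsi_hop_s,
        n_freq=config.n_freq,
        order=config.ar_order,
    )
    quantizer = Quantizer(config.quantizer_levels, config.entropy_log_base)
    return compute_indices(tfsi, quantizer)


def extract_features(
    segments: list[HRVSegment], config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Feature matrix: one row per segment (source, start_s, label, 8 indices).

    Per-segment failures are logged and the segment skipped, so one bad
    segment does not abort a batch; missing ratio indices appear as NaN.
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    for seg in segments:
        try:
            vec = segment_indices(seg, config)
        except ValueError as exc:
            log.warning("segment %s failed: %s", seg.source or "<unnamed>", exc)
            continue
        row = {"source": seg.source, "start_s": seg.start_s, "label": seg.group_label}
        row.update(
            {
                name: (np.nan if v is None else v)
                for name, v in zip(INDEX_NAMES, vec.as_tuple())
            }
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=["source", "start_s", "label", *INDEX_NAMES])
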
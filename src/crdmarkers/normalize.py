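"""Four-step two-channel array normalization and probe-to-gene annotation.

The normalization of the common-reference two-color design proceeds in a
fixed order:

1. natural-log transformation of raw spot intensities,
2. quantile normalization jointly over *all* scans (every sample-channel and
   reference-channel vector of every array shares one target distribution),
3. correction of each sample spot signal by its matching reference spot
   signal (subtraction on the ln scale, i.e. a ln-ratio),
4. arithmetic averaging of the replicate spots of each probe.

Quantile normalization ties are resolved deterministically: tied entries
receive the mean of the per-rank means at their tied ranks.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import REFERENCE_CHANNEL, SAMPLE_CHANNEL

logger = logging.getLogger(__name__)


def quantile_normalize(scans) -> pd.DataFrame:
    """Force every scan (column) onto the per-rank-mean distribution.

    Accepts a DataFrame, 2-D array, or sequence of equal-length vectors
    (columns = scans). After normalization the sorted values of every scan
    are identical; within-scan rank order is preserved, and values tied
    within a scan receive the mean of the rank means they jointly occupy.
    """
    if isinstance(scans, pd.DataFrame):
        frame = scans
        a = frame.to_numpy(float)
    else:
        vectors = [np.asarray(v, dtype=float) for v in scans]
        lengths = {len(v) for v in vectors}
        if len(lengths) > 1:
            raise DataError(f"scans have unequal lengths: {sorted(lengths)}")
        a = np.column_stack(vectors)
        frame = None
    if a.ndim != 2 or a.shape[1] < 2:
        raise DataError("quantile normalization requires >= 2 scans")

    rank_means = np.sort(a, axis=0).mean(axis=1)
    out = np.empty_like(a)
    n = a.shape[0]
    for j in range(a.shape[1]):
        col = a[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = rank_means
        uniques, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniques) < n:  # ties: average the rank means within each tie group
            sums = np.bincount(inverse, weights=assigned)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    if frame is not None:
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)
    return pd.DataFrame(out)


def ln_transform(probe_matrix: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform, rejecting non-positive intensities by location."""
    values = probe_matrix.to_numpy(float)
    bad = ~(values > 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise DataError(
            "non-positive intensity at probe/spot "
            f"{probe_matrix.index[i]}, scan {probe_matrix.columns[j]}"
        )
    return pd.DataFrame(np.log(values), index=probe_matrix.index, columns=probe_matrix.columns)


def reference_correct(ln_matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract the reference-channel ln signal from the sample-channel ln signal per spot."""
    channels = set(ln_matrix.columns.get_level_values("channel"))
    if channels != {SAMPLE_CHANNEL, REFERENCE_CHANNEL}:
        raise DataError(f"expected channels {{sample, reference}}, got {sorted(channels)}")
    sample = ln_matrix.xs(SAMPLE_CHANNEL, axis=1, level="channel")
    reference = ln_matrix.xs(REFERENCE_CHANNEL, axis=1, level="channel")
    if list(sample.columns) != list(reference.columns):
        raise DataError("sample and reference channels cover different sample sets")
    return sample - reference


def average_spots(spot_ratios: pd.DataFrame) -> pd.DataFrame:
    """Average replicate spots per probe (step 4); one output row per probe."""
    if spot_ratios.isna().any().any():
        missing = spot_ratios.index[spot_ratios.isna().any(axis=1)][0]
        raise DataError(f"spot present for only part of the samples: {missing}")
    counts = spot_ratios.groupby(level="probe_id", sort=False).size()
    if counts.nunique() > 1:
        logger.warning(
            "unequal spot counts across probes (%d..%d); averaging available spots",
            counts.min(),
            counts.max(),
        )
    return spot_ratios.groupby(level="probe_id", sort=False).mean()


def normalize_two_channel(probe_matrix: pd.DataFrame) -> pd.DataFrame:
    """Run normalization steps 1-4 on a spot-level two-channel probe matrix.

    Input rows are (probe_id, spot), columns (sample_id, channel). Returns
    the normalized expression matrix: probes x samples of ln-ratio values.
    """
    ln = ln_transform(probe_matrix)
    normalized = quantile_normalize(ln)
    ratios = reference_correct(normalized)
    return average_spots(ratios)


def read_annotation(path) -> dict[str, str | None]:
    """Load a 2-column probe->gene TSV; blank/NA second column = unannotated."""
    table = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if table.shape[1] < 2:
        raise DataError("annotation file needs two columns: probe_id, gene")
    probes, genes = table.iloc[:, 0], table.iloc[:, 1]
    return {
        p: (g if isinstance(g, str) and g.strip() else None)
        for p, g in zip(probes, genes)
    }


def annotate_and_deduplicate(
    probe_ids: Iterable[str], annotation: Mapping[str, str | None]
) -> list[str]:
    """Map probes to genes, dropping unannotated probes and collapsing duplicates.

    Multiple significant probes of one gene count as that single gene;
    probes without a gene are excluded. Returns sorted distinct symbols.
    """
    genes = {
        annotation.get(p)
        for p in probe_ids
        if annotation.get(p) not in (None, "", float("nan"))
    }
    genes.discard(None)
    return sorted(g for g in genes if isinstance(g, str) and g.strip())
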
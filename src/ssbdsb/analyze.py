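"""Descriptive class contrasts: per-residue frequency differences, gapped
dipeptide frequency differences with a reporting threshold, the per-region
physicochemical difference rate, and random-forest Gini importance summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CVResult
from .features import (
    compute_dipeptide,
    compute_oaac,
    dipeptide_names,
    encode_aaindex,
    REGION_NAMES,
)
from .seqio import ALPHABET, AAindexTable, LABEL_DSB, LABEL_SSB, LabeledDataset

logger = logging.getLogger(__name__)


@dataclass
class ClassContrast:
    """Per-item class means and their difference statistic."""

    item: str
    mean_class1: float
    mean_class2: float
    difference: float


def _class_indices(dataset: LabeledDataset) -> tuple[list[int], list[int]]:
    idx1 = [i for i, l in enumerate(dataset.labels) if l == LABEL_DSB]
    idx2 = [i for i, l in enumerate(dataset.labels) if l == LABEL_SSB]
    if not idx1 or not idx2:
        raise ValueError(
            f"both classes required, got counts {dataset.class_counts()}"
        )
    return idx1, idx2


def residue_frequency_contrast(dataset: LabeledDataset) -> list[ClassContrast]:
    """Mean raw residue frequency per class and the DSB-minus-SSB difference.

    Frequencies are the plain ``n_i / L`` values (no square-root transform):
    contrasts describe the composition itself, not the model encoding.
    """
    idx1, idx2 = _class_indices(dataset)
    # OAAC vectors are sqrt(freq); square to recover raw frequencies.
    freqs = np.vstack(
        [compute_oaac(r).values ** 2 for r in dataset.records]
    )
    m1 = freqs[idx1].mean(axis=0)
    m2 = freqs[idx2].mean(axis=0)
    return [
        ClassContrast(
            item=aa,
            mean_class1=float(m1[j]),
            mean_class2=float(m2[j]),
            difference=float(m1[j] - m2[j]),
        )
        for j, aa in enumerate(ALPHABET)
    ]


def dipeptide_frequency_contrast(
    dataset: LabeledDataset, s: int, report_threshold: float = 0.003
) -> list[ClassContrast]:
    """Per-dipeptide class means at interval ``s``; report entries whose
    absolute class difference reaches ``report_threshold``, sorted by
    absolute difference descending."""
    idx1, idx2 = _class_indices(dataset)
    values = np.vstack(
        [compute_dipeptide(r, s).values for r in dataset.records]
    )
    m1 = values[idx1].mean(axis=0)
    m2 = values[idx2].mean(axis=0)
    names = [n.split("_", 1)[1] for n in dipeptide_names(s)]
    entries = [
        ClassContrast(
            item=names[j],
            mean_class1=float(m1[j]),
            mean_class2=float(m2[j]),
            difference=float(m1[j] - m2[j]),
        )
        for j in range(400)
        if abs(m1[j] - m2[j]) >= report_threshold
    ]
    entries.sort(key=lambda c: abs(c.difference), reverse=True)
    return entries


def difference_rate(mean1: float, mean2: float) -> float:
    """Relative difference ``|m1 - m2| / max(m1, m2)``.

    Signed property scales can produce negative means, for which the ratio
    loses its [0, 1] interpretation; magnitudes are used instead (with a
    warning) and the rate is 0 when both magnitudes vanish.
    """
    if mean1 < 0 or mean2 < 0:
        logger.warning(
            "negative class mean (%.4g, %.4g); difference rate computed on "
            "magnitudes", mean1, mean2,
        )
        mean1, mean2 = abs(mean1), abs(mean2)
    top = max(mean1, mean2)
    if top == 0:
        return 0.0
    return abs(mean1 - mean2) / top


def property_difference_rate(
    dataset: LabeledDataset, table: AAindexTable
) -> list[ClassContrast]:
    """Per (property, region) relative class difference of region-mean
    property values — a ``n_properties x 6`` grid of entries."""
    idx1, idx2 = _class_indices(dataset)
    encoded = np.vstack(
        [encode_aaindex(r, table).values for r in dataset.records]
    )
    m1 = encoded[idx1].mean(axis=0)
    m2 = encoded[idx2].mean(axis=0)
    entries = []
    j = 0
    for pid in table.property_ids:
        for region in REGION_NAMES:
            entries.append(
                ClassContrast(
                    item=f"{pid}:{region}",
                    mean_class1=float(m1[j]),
                    mean_class2=float(m2[j]),
                    difference=difference_rate(float(m1[j]), float(m2[j])),
                )
            )
            j += 1
    return entries


def significant_properties(
    contrasts: list[ClassContrast], quantile: float = 0.75
) -> dict[str, list[str]]:
    """Per region, the properties whose difference rate is in the top
    ``1 - quantile`` fraction for that region (default: top 25%)."""
    by_region: dict[str, list[ClassContrast]] = {}
    for c in contrasts:
        region = c.item.rsplit(":", 1)[1]
        by_region.setdefault(region, []).append(c)
    out: dict[str, list[str]] = {}
    for region, items in by_region.items():
        cutoff = float(np.quantile([c.difference for c in items], quantile))
        out[region] = [
            c.item.rsplit(":", 1)[0] for c in items if c.difference >= cutoff
        ]
    return out


def gini_importance_summary(cv_result: CVResult) -> dict[str, pd.Series]:
    """Per family, the mean impurity-decrease importance of every feature
    across CV folds, sorted descending."""
    if cv_result.algorithm != "RF" or not cv_result.importances:
        raise ValueError(
            "Gini importances require a cross-validation run with the RF "
            "algorithm and collect_importances=True"
        )
    out: dict[str, pd.Series] = {}
    for fam, imp in cv_result.importances.items():
        series = pd.Series(imp, index=cv_result.feature_names[fam])
        out[fam] = series.sort_values(ascending=False)
    return out


def contrasts_to_frame(contrasts: list[ClassContrast]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "item": [c.item for c in contrasts],
            "mean_DSB": [c.mean_class1 for c in contrasts],
            "mean_SSB": [c.mean_class2 for c in contrasts],
            "difference": [c.difference for c in contrasts],
        }
    )
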
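"""Latency-based comparison methods sharing the preprocessing and CV machinery.

Two reference approaches against which the time-frequency pipeline is
compared:

* **PE-Latency** — each subject is reduced to the mean latency of peak
  instantaneous energy across surviving events, and subjects are split by
  2-means clustering of that single number;
* **P300-RF-Latency** — each subject is represented by the histogram of
  per-event peak-energy latencies inside the P300 window (250–500 ms by
  convention; the bounds are configurable) and classified with the same
  KNN leave-one-out machinery as the main pipeline.

Instantaneous energy is the squared band-passed amplitude; a peak is the
argmax sample, ties going to the earliest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import CVResult, loo_cv
from .timefreq import FeatureMatrix

__all__ = ["peak_energy_latencies", "pe_latency_classify", "p300_rf_latency_classify"]


class DataError(ValueError):
    pass


def peak_energy_latencies(epoch_set, electrode: str, window_ms=(0.0, 1000.0)) -> np.ndarray:
    """Per-event latency (ms post-stimulus) of maximum squared amplitude."""
    data = epoch_set.channel_data(electrode)
    if data.shape[0] == 0:
        raise DataError(f"subject {epoch_set.subject_id} has no surviving epochs")
    times = epoch_set.times_ms
    mask = (times >= window_ms[0]) & (times <= window_ms[1])
    energy = data[:, mask] ** 2
    # argmax returns the first maximum: ties go to the earliest sample
    return times[mask][np.argmax(energy, axis=1)]


def _metrics_from_predictions(pred: pd.Series, labels: pd.Series, params: dict) -> CVResult:
    correct = (pred == labels).to_numpy()
    is_pat = (labels == "patient").to_numpy()
    return CVResult(
        predictions=pred,
        labels=labels,
        distance_scores=pd.Series(np.nan, index=labels.index),
        accuracy=float(correct.mean()),
        specificity=float(correct[~is_pat].mean()) if (~is_pat).any() else float("nan"),
        sensitivity=float(correct[is_pat].mean()) if is_pat.any() else float("nan"),
        n_subjects=len(labels),
        params=params,
    )


def pe_latency_classify(
    epoch_sets, labels, electrode: str, seed: int = 0, window_ms=(0.0, 1000.0)
) -> CVResult:
    """2-means clustering of per-subject mean peak-energy latencies.

    Clusters are mapped to group labels by the majority label within each
    cluster; if both clusters prefer the same label, the mapping that
    maximizes accuracy is used.  Degenerate all-equal latencies are
    rejected.
    """
    labels = pd.Series(labels)
    means = {}
    for es in epoch_sets:
        means[es.subject_id] = float(np.mean(peak_energy_latencies(es, electrode, window_ms)))
    subjects = sorted(means)
    lat = np.array([means[s] for s in subjects])
    lab = labels.loc[subjects]
    if lab.value_counts().min() < 2:
        raise DataError("need >= 2 subjects per class")
    if np.allclose(lat, lat[0]):
        raise DataError("degenerate latencies: all subjects identical")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    assign = km.fit_predict(lat.reshape(-1, 1))
    best_pred, best_acc = None, -1.0
    for mapping in (("healthy", "patient"), ("patient", "healthy")):
        pred = pd.Series([mapping[a] for a in assign], index=subjects)
        acc = float((pred == lab).mean())
        if acc > best_acc:
            best_pred, best_acc = pred, acc
    # keep the majority mapping when it agrees; the max-accuracy mapping IS
    # the majority mapping whenever the two clusters prefer different labels
    return _metrics_from_predictions(
        best_pred, lab, {"method": "pe-latency", "electrode": electrode, "seed": seed}
    )


def p300_rf_latency_classify(
    epoch_sets,
    labels,
    electrode: str,
    k: int,
    p300_window_ms=(250.0, 500.0),
    n_bins: int = 10,
) -> CVResult:
    """KNN-LOO on histograms of peak-energy latencies in the P300 window.

    Each subject's feature vector is the count histogram (``n_bins`` fixed
    bins spanning the window) of per-event peak latencies searched within
    ``p300_window_ms``; rows therefore sum to the surviving event count.
    """
    labels = pd.Series(labels)
    edges = np.linspace(p300_window_ms[0], p300_window_ms[1], n_bins + 1)
    rows, index = [], []
    for es in epoch_sets:
        lat = peak_energy_latencies(es, electrode, p300_window_ms)
        hist, _ = np.histogram(lat, bins=edges)
        rows.append(hist.astype(float))
        index.append(es.subject_id)
    values = pd.DataFrame(np.vstack(rows), index=index)
    fm = FeatureMatrix(
        values=values,
        labels=labels.reindex(index),
        provenance={"method": "p300-rf-latency", "electrode": electrode, "window": p300_window_ms},
    )
    cv = loo_cv(fm, k)
    cv.params.update(fm.provenance)
    return cv
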
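"""Exhaustive feature-window optimization and marginal analyses.

The discrimination pipeline is run over the full cross product of
electrode × time window × frequency band × number of events × K, producing
a dense result grid whose cells are leave-one-out cross-validated metrics.
Examining the grid reveals both the best configuration and, via marginals,
how discrimination power distributes along each parameter dimension
(electrode ranking, event-count curve, time-window curve, band curve).

Cells are computed independently of evaluation order and deterministically;
ties in the best-cell report are broken by (highest accuracy, earliest
window start, lowest band, fewest events, smallest K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import loo_cv
from .timefreq import FeatureMatrix, stockwell

__all__ = ["GridResult", "run_grid", "marginal", "early_late_profile"]


class ConfigurationError(ValueError):
    pass


CELL_COLUMNS = [
    "electrode", "t_start", "t_end", "f_low", "f_high", "n_events", "k",
    "accuracy", "specificity", "sensitivity", "margin", "n_subjects",
]


@dataclass
class GridResult:
    """Dense cross-validated result grid.

    ``table`` has one row per cell (coordinate + metrics); ``cells`` maps
    the coordinate tuple (electrode, t_start, t_end, f_low, f_high,
    n_events, k) to the full CVResult.
    """

    axes: dict
    table: pd.DataFrame
    cells: dict = field(repr=False, default_factory=dict)

    def best_cell(self) -> pd.Series:
        """Top-accuracy cell under the deterministic tie-break.

        Accuracy saturates at 1 over many neighbouring cells once classes
        separate cleanly, so accuracy ties are broken first by the
        continuous neighbor margin (which keeps growing with separation)
        and only then by position (earliest window start, lowest band,
        fewest events, smallest K).
        """
        t = self.table.sort_values(
            ["accuracy", "margin", "t_start", "f_low", "n_events", "k"],
            ascending=[False, False, True, True, True, True],
            kind="stable",
        )
        return t.iloc[0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def run_grid(
    epoch_sets,
    labels,
    electrodes,
    windows,
    n_events_axis,
    k_axis,
    kernel: str = "classic",
    mode: str = "average-then-transform",
) -> GridResult:
    """Populate the (electrode × window × n_events × K) result grid.

    ``epoch_sets`` is one EpochSet per subject and ``labels`` maps subject
    id → group.  Per-subject S-transforms of averaged epochs are computed
    once per (electrode, n_events) and shared by every window cell, so the
    grid scales with the number of transforms, not the number of cells.
    """
    if not (len(electrodes) and len(windows) and len(n_events_axis) and len(k_axis)):
        raise ConfigurationError("all grid axes must be non-empty")
    for el in electrodes:
        for es in epoch_sets:
            if el not in es.channel_labels:
                raise ConfigurationError(f"electrode {el!r} absent from subject {es.subject_id}")
    labels = pd.Series(labels)
    fmax = max(w.f_high for w in windows)

    # cache: (electrode, n_events) -> {subject: STFeatureMap}
    st_cache: dict = {}

    def _maps(electrode, n_events):
        key = (electrode, n_events)
        if key not in st_cache:
            maps = {}
            for es in epoch_sets:
                data = es.channel_data(electrode)
                if data.shape[0] < n_events:
                    continue
                if mode == "average-then-transform":
                    frame = data[:n_events].mean(axis=0)
                    maps[es.subject_id] = stockwell(
                        frame, es.fs, t0_offset_ms=es.t0_offset_ms, fmax=fmax, kernel=kernel
                    )
                else:
                    acc = None
                    for ep in data[:n_events]:
                        st = stockwell(
                            ep, es.fs, t0_offset_ms=es.t0_offset_ms, fmax=fmax, kernel=kernel
                        )
                        acc = st.magnitudes if acc is None else acc + st.magnitudes
                    st0 = stockwell(
                        data[0], es.fs, t0_offset_ms=es.t0_offset_ms, fmax=fmax, kernel=kernel
                    )
                    st0.magnitudes = acc / n_events
                    maps[es.subject_id] = st0
            st_cache[key] = maps
        return st_cache[key]

    rows, cells = [], {}
    for el in electrodes:
        for n_ev in n_events_axis:
            maps = _maps(el, n_ev)
            for w in windows:
                feats = {sid: m.window(w).ravel() for sid, m in maps.items()}
                values = pd.DataFrame(
                    np.vstack(list(feats.values())), index=list(feats.keys())
                )
                fm = FeatureMatrix(
                    values=values,
                    labels=labels.reindex(values.index),
                    provenance={"electrode": el, "window": w.as_tuple(), "n_events": n_ev},
                )
                for k in k_axis:
                    cv = loo_cv(fm, k)
                    coord = (el, *w.as_tuple(), n_ev, k)
                    cells[coord] = cv
                    rows.append(
                        dict(
                            zip(
                                CELL_COLUMNS,
                                (*coord, cv.accuracy, cv.specificity, cv.sensitivity,
                                 cv.margin, cv.n_subjects),
                            )
                        )
                    )
    table = pd.DataFrame(rows, columns=CELL_COLUMNS)
    axes = {
        "electrode": list(electrodes),
        "windows": [w.as_tuple() for w in windows],
        "n_events": list(n_events_axis),
        "k": list(k_axis),
    }
    return GridResult(axes=axes, table=table, cells=cells)


_DIMENSION_KEYS = {
    "electrode": ["electrode"],
    "window": ["t_start", "t_end", "f_low", "f_high"],
    "time_window": ["t_start", "t_end"],
    "band": ["f_low", "f_high"],
    "n_events": ["n_events"],
    "k": ["k"],
}


def marginal(gr: GridResult, dimension: str) -> pd.DataFrame:
    """Mean and best accuracy for each value of one grid dimension.

    ``dimension`` is one of electrode, window, time_window, band, n_events,
    k; the mean/max run over all the other dimensions.
    """
    if dimension not in _DIMENSION_KEYS:
        raise ConfigurationError(
            f"unknown dimension {dimension!r}; choose from {sorted(_DIMENSION_KEYS)}"
        )
    keys = _DIMENSION_KEYS[dimension]
    g = gr.table.groupby(keys, sort=True)["accuracy"].agg(["mean", "max"]).reset_index()
    return g.rename(columns={"mean": "mean_accuracy", "max": "best_accuracy"})


def early_late_profile(epoch_sets, labels, electrode: str, n_early: int = 5, n_late: int = 5):
    """Group-averaged epoch waveforms for early, late, and all trials.

    For each subject with at least ``n_early + n_late`` surviving trials the
    first ``n_early``, last ``n_late`` and all epochs on ``electrode`` are
    averaged; subject averages are then averaged within group.  Returns
    ``(profiles, skipped)`` where profiles maps group →
    {"early", "late", "all", "times_ms"}.
    """
    labels = pd.Series(labels)
    acc: dict = {}
    skipped = []
    times = None
    for es in epoch_sets:
        data = es.channel_data(electrode)
        if data.shape[0] < n_early + n_late:
            skipped.append(es.subject_id)
            continue
        times = es.times_ms
        group = labels.loc[es.subject_id]
        entry = acc.setdefault(group, {"early": [], "late": [], "all": []})
        entry["early"].append(data[:n_early].mean(axis=0))
        entry["late"].append(data[-n_late:].mean(axis=0))
        entry["all"].append(data.mean(axis=0))
    profiles = {
        group: {
            "early": np.mean(entry["early"], axis=0),
            "late": np.mean(entry["late"], axis=0),
            "all": np.mean(entry["all"], axis=0),
            "times_ms": times,
        }
        for group, entry in acc.items()
    }
    return profiles, skipped
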
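"""End-to-end two-group analysis: signals in, statistics out.

`analyze_group` reduces one group's recordings to spectra, band-wise
lagged-phase-coherence networks and graph metrics; `compare_groups` then
produces the between-group readout: 1/f slope contrast, mixed
group x band ANOVAs on the node metrics, per-band edgewise significance
maps, connectivity/functional-distance vs physical-distance regressions,
and cross-frequency coupling of shortest-path structure.

Group reduction supports two conventions (the field uses both): pooling
epochs across recordings before cross-spectral averaging
(``average_mode="cross_spectra"``), or averaging per-recording
connectivity matrices (``average_mode="networks"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import CANONICAL_BANDS, HIGH_BANDS, LOW_BANDS
from .connectivity import connectivity_matrices
from .graphs import graph_metrics
from .recording import Recording
from .spectral import (EpochSet, SpectralEstimate, compare_slopes, epoch,
                       power_spectrum)
from .stats import (compare_correlations, compare_regression_slopes,
                    cross_frequency_coupling, distance_regression,
                    edgewise_group_map, group_band_anova, physical_distance)


@dataclass
class GroupAnalysis:
    """One group's reduced data: spectra, networks, metrics per band."""

    ps: SpectralEstimate
    connectivity: dict[str, np.ndarray]
    distance: dict[str, np.ndarray]
    strength: np.ndarray           # (n_nodes, n_bands)
    clustering: np.ndarray         # (n_nodes, n_bands)
    local_efficiency: np.ndarray   # (n_nodes, n_bands)
    char_path_length: np.ndarray   # (n_bands,)
    n_epochs: int
    labels: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None


def _pooled_epochs(recordings: list[Recording], epoch_length_s: float,
                   overlap: float) -> EpochSet:
    sets = [epoch(r, epoch_length_s, overlap) for r in recordings]
    rate = sets[0].rate
    if any(s.rate != rate for s in sets):
        raise ValueError("recordings must share a sampling rate")
    return EpochSet(epochs=np.concatenate([s.epochs for s in sets]),
                    rate=rate, epoch_length_s=epoch_length_s)


def analyze_group(recordings: list[Recording], bands=CANONICAL_BANDS,
                  epoch_length_s: float = 2.0, overlap: float = 0.0,
                  average_mode: str = "cross_spectra") -> GroupAnalysis:
    """Reduce a group of recordings to networks and graph metrics."""
    if not recordings:
        raise ValueError("empty group")
    if average_mode not in ("cross_spectra", "networks"):
        raise ValueError("average_mode must be 'cross_spectra' or 'networks'")
    pooled = _pooled_epochs(recordings, epoch_length_s, overlap)
    ps = power_spectrum(pooled)

    if average_mode == "cross_spectra":
        conn = {name: cm.w for name, cm in
                connectivity_matrices(pooled, bands).items()}
    else:
        per_rec = [connectivity_matrices(
            epoch(r, epoch_length_s, overlap), bands) for r in recordings]
        conn = {b.name: np.mean([m[b.name].w for m in per_rec], axis=0)
                for b in bands}

    metrics = {name: graph_metrics(w) for name, w in conn.items()}
    names = [b.name for b in bands]
    return GroupAnalysis(
        ps=ps,
        connectivity=conn,
        distance={n: metrics[n].distance for n in names},
        strength=np.column_stack([metrics[n].strength for n in names]),
        clustering=np.column_stack([metrics[n].clustering for n in names]),
        local_efficiency=np.column_stack(
            [metrics[n].local_efficiency for n in names]),
        char_path_length=np.array(
            [metrics[n].char_path_length for n in names]),
        n_epochs=pooled.n_epochs,
        labels=recordings[0].labels,
        coords=recordings[0].coords,
    )


def compare_groups(group_a: list[Recording], group_b: list[Recording],
                   bands=CANONICAL_BANDS, epoch_length_s: float = 2.0,
                   overlap: float = 0.0, fit_range=(2.0, 43.0),
                   alpha_level: float = 0.05,
                   average_mode: str = "cross_spectra") -> dict:
    """Full between-group comparison; returns a nested results mapping."""
    ga = analyze_group(group_a, bands, epoch_length_s, overlap, average_mode)
    gb = analyze_group(group_b, bands, epoch_length_s, overlap, average_mode)
    names = [b.name for b in bands]
    pdist_mat = physical_distance(ga.coords)

    slope_cmp = compare_slopes(ga.ps, gb.ps, *fit_range)
    results: dict = {
        "bands": names,
        "slope_comparison": {
            "t": slope_cmp.statistic, "p": slope_cmp.p_value,
            "alpha_diff": slope_cmp.alpha_diff,
        },
        "anova": {},
        "char_path_length": {"A": ga.char_path_length.tolist(),
                             "B": gb.char_path_length.tolist()},
        "mean_strength": {"A": ga.strength.mean(axis=0).tolist(),
                          "B": gb.strength.mean(axis=0).tolist()},
        "edgewise": {},
        "distance_regression": {},
        "cross_frequency": {},
    }

    for metric, va, vb in (
            ("strength", ga.strength, gb.strength),
            ("clustering", ga.clustering, gb.clustering),
            ("local_efficiency", ga.local_efficiency, gb.local_efficiency)):
        res = group_band_anova(va, vb, band_names=names)
        results["anova"][metric] = {
            "group": vars(res.group),
            "interaction": vars(res.interaction),
            "contrasts": [vars(c) for c in res.contrasts],
        }

    for name in names:
        emap = edgewise_group_map(
            ga.connectivity[name], gb.connectivity[name],
            ga.distance[name], gb.distance[name],
            ga.n_epochs, gb.n_epochs, alpha_level=alpha_level)
        results["edgewise"][name] = {
            "A_longer": emap.n_a_longer, "B_longer": emap.n_b_longer,
            "not_significant": emap.n_not_significant,
            "map": emap.map,
        }
        reg_a = distance_regression(ga.connectivity[name], pdist_mat)
        reg_b = distance_regression(gb.connectivity[name], pdist_mat)
        inter = compare_regression_slopes(
            ga.connectivity[name], pdist_mat,
            gb.connectivity[name], pdist_mat)
        results["distance_regression"][name] = {
            "A": vars(reg_a), "B": vars(reg_b),
            "slope_interaction": vars(inter),
        }

    low = [n for n in names if n in LOW_BANDS]
    high = [n for n in names if n in HIGH_BANDS]
    for lo in low:
        for hi in high:
            ra = cross_frequency_coupling(ga.distance[lo], ga.distance[hi],
                                          lo, hi)
            rb = cross_frequency_coupling(gb.distance[lo], gb.distance[hi],
                                          lo, hi)
            z, p = compare_correlations(ra.r, ra.n, rb.r, rb.n)
            results["cross_frequency"][f"{lo}-{hi}"] = {
                "r_A": ra.r, "r_B": rb.r, "n": ra.n, "z": z, "p": p,
            }
    return results
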
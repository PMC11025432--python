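"""Median age-at-diagnosis profiles per disease and per cluster.

The disease-level median is taken over each patient's earliest recorded
diagnosis age for that disease.  The cluster-level median pools all
events of member diseases (event-weighted); a disease-weighted variant
(median of the member-disease medians) is available as a sensitivity
switch.
"""

from __future__ import annotations

import pandas as pd

from .types import ClusterMap, ReferentialError


def median_onset_by_disease(events: pd.DataFrame) -> pd.DataFrame:
    """One row per disease with >= 1 event: median onset age and event count.

    Medians of even-sized samples use the midpoint of the two central
    values.
    """
    if len(events) == 0:
        raise ValueError("no diagnosis events")
    g = events.groupby("disease_id")["age_at_diagnosis"]
    out = pd.DataFrame(
        {
            "unit_id": g.median().index,
            "level": "disease",
            "median_age": g.median().to_numpy(),
            "n_events": g.size().to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def median_onset_by_cluster(
    events: pd.DataFrame, cluster_map: ClusterMap, weighting: str = "event"
) -> pd.DataFrame:
    """One row per cluster: median onset age over member diseases' events.

    ``weighting="event"`` pools all events of member diseases;
    ``weighting="disease"`` instead takes the median of the member-disease
    medians.
    """
    unknown = set(events["disease_id"]) - set(cluster_map.disease_ids)
    if unknown:
        raise ReferentialError(f"unknown diseases in events: {sorted(unknown)[:5]}")
    cl = events["disease_id"].map(cluster_map.disease_to_cluster)
    if weighting == "event":
        g = events.groupby(cl)["age_at_diagnosis"]
        med, n = g.median(), g.size()
    elif weighting == "disease":
        per_disease = events.groupby(["disease_id"])["age_at_diagnosis"].median()
        d2c = cluster_map.disease_to_cluster
        med = per_disease.groupby(per_disease.index.map(d2c)).median()
        n = events.groupby(cl).size()
    else:
        raise ValueError("weighting must be 'event' or 'disease'")
    out = pd.DataFrame(
        {
            "unit_id": med.index,
            "level": "cluster",
            "median_age": med.to_numpy(),
            "n_events": n.reindex(med.index).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def onset_table(
    events: pd.DataFrame, cluster_map: ClusterMap, weighting: str = "event"
) -> pd.DataFrame:
    """Combined cluster + disease onset table, ordered by cluster then disease."""
    diseases = median_onset_by_disease(events)
    diseases["cluster_id"] = diseases["unit_id"].map(cluster_map.disease_to_cluster)
    clusters = median_onset_by_cluster(events, cluster_map, weighting)
    clusters["cluster_id"] = clusters["unit_id"]
    order = {c: i for i, c in enumerate(cluster_map.cluster_ids)}
    out = pd.concat([clusters, diseases], ignore_index=True)
    out["_ord"] = out["cluster_id"].map(order)
    out = out.sort_values(["_ord", "level", "unit_id"]).drop(columns="_ord")
    return out.reset_index(drop=True)
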
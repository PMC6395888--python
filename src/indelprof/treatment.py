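"""Indel-profile and efficiency comparisons across treatment conditions.

Two normalizations serve two questions. Library-size normalization
(count / total reads for the condition) asks how each indel contributes to
efficiency changes; indels below 1% of the library in every condition are
noise-filtered. Size-factor normalization (count / total indels detected in
the condition) asks whether the *profile* shifts over and above efficiency,
restricted to the 10 most frequent indels of the untreated condition.
Efficiency changes are reported as log2 fold-change versus untreated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNTREATED = "NT"

SERIES_COLUMNS = [
    "site_id", "condition", "dose", "replicate", "event_name",
    "inserted_seq", "count", "library_size", "efficiency",
]


@dataclass
class TreatmentSeries:
    """Long-format per-site measurements across ordered conditions.

    ``data`` holds one row per (condition, replicate, event) with raw count,
    library size and the condition/replicate efficiency; ``conditions`` fixes
    the dose order, with the untreated label first.
    """

    site_id: str
    conditions: list  # ordered list[(label, dose)]
    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = set(SERIES_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"series data missing columns: {sorted(missing)}")
        labels = [c for c, _ in self.conditions]
        extra = set(self.data["condition"]) - set(labels)
        if extra:
            raise ValueError(f"data contains unlisted conditions: {sorted(extra)}")
        for _, grp in self.data.groupby(["condition", "replicate"]):
            if grp["count"].sum() > grp["library_size"].iloc[0]:
                raise ValueError("library_size smaller than total indel count")

    @property
    def condition_labels(self) -> list[str]:
        return [c for c, _ in self.conditions]


def series_from_profiles(
    site_id: str,
    conditions: list,
    profiles: dict,  # (condition, replicate) -> SiteIndelProfile
    efficiencies: dict,  # (condition, replicate) -> float
) -> TreatmentSeries:
    rows = []
    dose_of = dict(conditions)
    for (condition, replicate), profile in profiles.items():
        for event, count in profile.counts.items():
            rows.append(
                {
                    "site_id": site_id,
                    "condition": condition,
                    "dose": dose_of[condition],
                    "replicate": replicate,
                    "event_name": event.name,
                    "inserted_seq": event.inserted_seq,
                    "count": count,
                    "library_size": profile.library_size,
                    "efficiency": efficiencies[(condition, replicate)],
                }
            )
    return TreatmentSeries(
        site_id=site_id, conditions=conditions,
        data=pd.DataFrame(rows, columns=SERIES_COLUMNS),
    )


def normalize_by_library(counts: dict, library_size: int) -> dict:
    """Raw event counts divided by the condition's library size."""
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    return {e: c / library_size for e, c in counts.items()}


def _library_normalized(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["norm_count"] = out["count"] / out["library_size"]
    return out


def filter_minor_indels(
    series: TreatmentSeries, threshold: float = 0.01, mode: str = "library_fraction"
) -> TreatmentSeries:
    """Drop events below threshold in *every* condition.

    ``mode='library_fraction'``: an event survives if its library-normalized
    count reaches ``threshold`` (default 1% of library size) in at least one
    condition (replicates averaged). ``mode='normalized_count'``: companion
    rule keeping events whose per-million-style normalized count reaches 1
    in any condition.
    """
    df = _library_normalized(series.data)
    if df.empty:
        return TreatmentSeries(series.site_id, series.conditions, series.data.copy())
    key = ["event_name", "inserted_seq"]
    per_cond = df.groupby(key + ["condition"])["norm_count"].mean().reset_index()
    if mode == "library_fraction":
        ok = per_cond[per_cond["norm_count"] >= threshold]
    elif mode == "normalized_count":
        per_cond["scaled"] = per_cond["norm_count"] * 1e6
        ok = per_cond[per_cond["scaled"] >= 1.0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = set(map(tuple, ok[key].itertuples(index=False)))
    mask = series.data[key].apply(tuple, axis=1).isin(keep)
    return TreatmentSeries(
        series.site_id, series.conditions, series.data[mask].reset_index(drop=True)
    )


def efficiency_fold_change(series: TreatmentSeries) -> pd.DataFrame:
    """log2(efficiency / untreated efficiency), per replicate and averaged."""
    eff = series.data[
        ["condition", "dose", "replicate", "efficiency"]
    ].drop_duplicates()
    nt = eff[eff["condition"] == UNTREATED]
    if nt.empty or (nt["efficiency"] <= 0).any():
        raise ValueError("untreated (NT) condition with positive efficiency required")
    nt_by_rep = dict(zip(nt["replicate"], nt["efficiency"]))
    nt_mean = float(nt["efficiency"].mean())
    rows = []
    for row in eff.itertuples(index=False):
        base = nt_by_rep.get(row.replicate, nt_mean)
        rows.append(
            {
                "site_id": series.site_id,
                "condition": row.condition,
                "dose": row.dose,
                "replicate": row.replicate,
                "log2_fc": float(np.log2(row.efficiency / base)),
            }
        )
    per_rep = pd.DataFrame(rows)
    averaged = (
        per_rep.groupby(["site_id", "condition", "dose"], sort=False)["log2_fc"]
        .mean()
        .reset_index()
        .assign(replicate="mean")
    )
    return pd.concat([per_rep, averaged], ignore_index=True)


def profile_relative_frequencies(
    series: TreatmentSeries, top_n: int = 10
) -> pd.DataFrame:
    """Size-factor-normalized frequencies restricted to top untreated events.

    The size factor is the total number of indels detected in a condition
    (replicates pooled); only the ``top_n`` most frequent events of the
    untreated condition are tracked.
    """
    df = series.data
    nt = df[df["condition"] == UNTREATED]
    if nt.empty:
        raise ValueError("untreated (NT) condition required")
    key = ["event_name", "inserted_seq"]
    nt_totals = nt.groupby(key)["count"].sum().sort_values(ascending=False)
    top = set(map(tuple, nt_totals.head(top_n).index.to_flat_index()))
    size_factor = df.groupby("condition")["count"].sum()
    rows = []
    for (cond, name, ins), grp in df.groupby(["condition"] + key, sort=False):
        if (name, ins) not in top:
            continue
        rows.append(
            {
                "site_id": series.site_id,
                "condition": cond,
                "dose": grp["dose"].iloc[0],
                "event_name": name,
                "inserted_seq": ins,
                "relative_frequency": grp["count"].sum() / size_factor[cond],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["site_id", "condition", "dose", "event_name",
                 "inserted_seq", "relative_frequency"],
    )


def rank_frequency_trajectory(
    series: TreatmentSeries, ranks: tuple = (1, 2, 3)
) -> tuple[pd.DataFrame, bool]:
    """Frequency-vs-dose trajectories for the untreated top-ranked indels.

    Rank identity is fixed in the untreated condition and those events are
    tracked across doses (mean +/- SD across replicates; a single replicate
    reports SD 0). Separately, the per-condition commonest event is compared
    with the untreated commonest; a change raises the identity-change flag.
    """
    df = series.data
    nt = df[df["condition"] == UNTREATED]
    if nt.empty:
        raise ValueError("untreated (NT) condition required")
    key = ["event_name", "inserted_seq"]
    nt_order = (
        nt.groupby(key)["count"].sum().sort_values(ascending=False).index.to_list()
    )
    if len(nt_order) < max(ranks):
        raise ValueError(f"untreated profile has only {len(nt_order)} events")
    tracked = {r: tuple(nt_order[r - 1]) for r in ranks}

    rows = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=False):
        total = grp["count"].sum()
        freqs = grp.groupby(key)["count"].sum() / total
        for r, ev in tracked.items():
            rows.append(
                {
                    "site_id": series.site_id,
                    "condition": cond,
                    "dose": grp["dose"].iloc[0],
                    "replicate": rep,
                    "rank": r,
                    "event_name": ev[0],
                    "frequency": float(freqs.get(ev, 0.0)),
                }
            )
    per_rep = pd.DataFrame(rows)
    agg = (
        per_rep.groupby(["site_id", "condition", "dose", "rank", "event_name"])
        ["frequency"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=0)))
        .reset_index()
    )

    # identity-change flag: does any condition's commonest differ from NT's?
    identity_change = False
    nt_commonest = tuple(nt_order[0])
    for cond, grp in df.groupby("condition", sort=False):
        top = grp.groupby(key)["count"].sum().sort_values(ascending=False)
        if tuple(top.index[0]) != nt_commonest:
            identity_change = True
    return agg, identity_change
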
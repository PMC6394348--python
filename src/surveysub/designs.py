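"""Stage-3 age sub-sampling designs.

Four designs draw the aged sub-sample from a virtual population at a random
preselection of sites (the same preselection for every design compared):

* ``random`` (RS): a fixed number of fish per preselected site, uniformly
  without replacement, regardless of length, sex or area;
* ``length_stratified`` (LSS): a quota of fish per (1-cm length bin, sex,
  NW/SE area) cell, filled by visiting sites in cruise order — so sites late
  in the route contribute nothing once quotas are exhausted;
* ``census``: every fish at every preselected site;
* ``random_matched``: an RS sample thinned uniformly to match another
  design's total sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import VirtualPopulation

DESIGN_KINDS = ("random", "length_stratified", "census", "random_matched")


@dataclass(frozen=True)
class DesignConfig:
    """Stage-3 design parameters.

    ``site_fraction`` is the proportion of survey sites preselected for age
    collection; ``rs_per_site`` the RS per-site take; ``lss_quota`` the LSS
    per-cell quota over (1-cm bin x sex x area) cells.
    """

    kind: str = "random"
    site_fraction: float = 0.5
    rs_per_site: int = 4
    lss_quota: int = 3

    def __post_init__(self):
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"kind must be one of {DESIGN_KINDS}")
        if not 0 < self.site_fraction <= 1:
            raise ValueError("site_fraction must be in (0, 1]")
        if self.rs_per_site < 1 or self.lss_quota < 1:
            raise ValueError("quotas must be >= 1")


@dataclass
class SubSample:
    """A stage-3 sub-sample: fish-level records plus site bookkeeping."""

    design: DesignConfig
    records: pd.DataFrame
    sites_visited: tuple[str, ...]
    sites_skipped: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.records)


def select_age_sites(
    sites: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Preselect floor(fraction * n) sites uniformly without replacement."""
    if len(sites) == 0:
        raise ValueError("no sites to preselect from")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = int(np.floor(fraction * len(sites)))
    chosen = rng.choice(sites["site_id"].to_numpy(), size=n, replace=False)
    return tuple(sorted(chosen))


def random_subsample(
    pop: VirtualPopulation,
    preselected: tuple[str, ...],
    config: DesignConfig,
    rng: np.random.Generator,
) -> SubSample:
    """RS: min(rs_per_site, catch) fish per preselected site, uniform."""
    if config.kind != "random":
        raise ValueError("config.kind must be 'random'")
    fish = pop.fish
    by_site = {sid: idx.to_numpy() for sid, idx in fish.groupby("site_id").groups.items()}
    rows = []
    skipped = []
    for sid in preselected:
        at_site = by_site.get(sid, np.array([], dtype=int))
        if len(at_site) == 0:
            skipped.append(sid)
            continue
        take = min(config.rs_per_site, len(at_site))
        rows.append(rng.choice(at_site, size=take, replace=False))
    records = fish.loc[np.concatenate(rows)] if rows else fish.iloc[:0]
    return SubSample(config, records.reset_index(drop=True), tuple(preselected), tuple(skipped))


def stratified_subsample(
    pop: VirtualPopulation,
    preselected: tuple[str, ...],
    config: DesignConfig,
    rng: np.random.Generator,
) -> SubSample:
    """LSS: fill per-(cm bin, sex, area) quotas in cruise (route) order.

    Within a site, fish are inspected in a random order; a cell with
    remaining quota takes fish until filled and never exceeds
    ``lss_quota``.  Sites contributing zero fish go to ``sites_skipped``.
    """
    if config.kind != "length_stratified":
        raise ValueError("config.kind must be 'length_stratified'")
    fish = pop.fish
    route = (
        pop.sites[pop.sites["site_id"].isin(preselected)]
        .sort_values("route_index", kind="stable")["site_id"]
        .to_numpy()
    )
    cm = fish["cm_bin"].to_numpy()
    sex = fish["sex"].to_numpy(dtype=object)
    area = fish["area"].to_numpy(dtype=object)
    by_site = {sid: idx.to_numpy() for sid, idx in fish.groupby("site_id").groups.items()}
    quota: dict[tuple, int] = {}
    taken = []
    skipped = []
    for sid in route:
        at_site = by_site.get(sid, np.array([], dtype=int))
        got_here = 0
        for i in rng.permutation(at_site):
            key = (int(cm[i]), sex[i], area[i])
            if quota.get(key, 0) < config.lss_quota:
                quota[key] = quota.get(key, 0) + 1
                taken.append(i)
                got_here += 1
        if got_here == 0:
            skipped.append(sid)
    records = fish.loc[taken] if taken else fish.iloc[:0]
    return SubSample(config, records.reset_index(drop=True), tuple(preselected), tuple(skipped))


def census_subsample(pop: VirtualPopulation, preselected: tuple[str, ...]) -> SubSample:
    """Census: every fish at every preselected site (no sub-sampling)."""
    config = DesignConfig(kind="census")
    records = pop.fish[pop.fish["site_id"].isin(preselected)]
    empty = tuple(s for s in preselected if s not in set(records["site_id"]))
    return SubSample(config, records.reset_index(drop=True), tuple(preselected), empty)


def match_sample_size(rs: SubSample, target_n: int, rng: np.random.Generator) -> SubSample:
    """Thin an RS sample uniformly to exactly ``target_n`` records."""
    if target_n > len(rs.records):
        raise ValueError(f"target_n={target_n} exceeds available {len(rs.records)} records")
    keep = np.sort(rng.choice(len(rs.records), size=target_n, replace=False))
    config = DesignConfig(
        kind="random_matched",
        site_fraction=rs.design.site_fraction,
        rs_per_site=rs.design.rs_per_site,
        lss_quota=rs.design.lss_quota,
    )
    return SubSample(config, rs.records.iloc[keep].reset_index(drop=True), rs.sites_visited, rs.sites_skipped)
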
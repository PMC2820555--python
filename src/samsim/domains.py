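"""Discretization of concentration fields into OC and SCD domains.

The continuous fields are thresholded relative to the wild-type equilibrium
on the same tissue: a cell belongs to the organizing centre (OC) when its
WUS level reaches ``delta_wus`` times the wild-type maximum, and to the
stem cell domain (SCD) when it is competent and its stemness reaches
``delta_st`` times the wild-type maximum (defaults 0.31 and 0.21).  The
resulting cell sets are summarized by counts, connected components on the
cell graph, centroids and mutual overlap/adjacency — the quantities the
scenario catalogue's expected-outcome checks are written against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .geometry import MeristemGeometry
from .model import SPECIES, WUS, STEMNESS

__all__ = [
    "DomainLabeling",
    "label_domains",
    "summarize_sweep",
    "check_outcome",
    "OutcomeReport",
    "DELTA_ST",
    "DELTA_WUS",
]

#: default discretization thresholds, relative to wild-type maxima
DELTA_ST = 0.21
DELTA_WUS = 0.31


@dataclass
class DomainLabeling:
    """Thresholded OC/SCD cell sets with connectivity and position."""

    time: float
    oc_cells: np.ndarray            # positional indices, sorted
    scd_cells: np.ndarray
    oc_count: int
    scd_count: int
    oc_components: int
    scd_components: int
    oc_centroid: np.ndarray | None  # (2,) or None if empty
    scd_centroid: np.ndarray | None
    oc_tip_distance: float          # mean geodesic hops from tip (nan if empty)
    scd_tip_distance: float
    overlap_cells: np.ndarray
    adjacency_flag: bool            # OC and SCD share >= 1 edge, no overlap
    wus_total: float
    stemness_total: float
    tip_in_oc: bool

    @property
    def overlap_count(self) -> int:
        return int(self.overlap_cells.size)

    def overlap_fraction(self) -> float:
        """Overlap relative to the smaller of the two domains."""
        denom = min(self.oc_count, self.scd_count)
        return self.overlap_count / denom if denom else 0.0


def _components(cells: np.ndarray, geometry: MeristemGeometry) -> int:
    if cells.size == 0:
        return 0
    sub = geometry.adjacency_matrix()[np.ix_(cells, cells)]
    n, _ = connected_components(sub, directed=False)
    return int(n)


def _touching(a: np.ndarray, b: np.ndarray,
              geometry: MeristemGeometry) -> bool:
    if a.size == 0 or b.size == 0:
        return False
    sa, sb = set(a.tolist()), set(b.tolist())
    for i, j in geometry.edges:
        if (i in sa and j in sb) or (j in sa and i in sb):
            return True
    return False


def label_domains(state: np.ndarray,
                  wildtype_reference: np.ndarray,
                  delta_st: float = DELTA_ST,
                  delta_wus: float = DELTA_WUS,
                  geometry: MeristemGeometry | None = None,
                  time: float = 0.0) -> DomainLabeling:
    """Label OC and SCD cells of ``state`` against a wild-type reference.

    ``wildtype_reference`` is a wild-type stage-1 equilibrium; only its
    per-species maxima enter the thresholds, so it may live on a larger
    tissue than ``state`` (e.g. the intact tissue when ``state`` is an
    ablated remnant).
    """
    if geometry is None:
        raise ValueError("geometry is required")
    if state.shape[0] != len(SPECIES):
        raise ValueError("state must have one row per species")
    if state.shape[1] != geometry.n_cells:
        raise ValueError("state does not match geometry")
    if wildtype_reference.shape[0] != len(SPECIES):
        raise ValueError("reference must have one row per species")
    if wildtype_reference.shape[1] < geometry.n_cells:
        raise ValueError("reference tissue smaller than state tissue")

    wus_ref = float(np.max(wildtype_reference[WUS]))
    st_ref = float(np.max(wildtype_reference[STEMNESS]))
    oc = np.flatnonzero(state[WUS] >= delta_wus * wus_ref)
    scd = np.flatnonzero(geometry.competent
                         & (state[STEMNESS] >= delta_st * st_ref))
    overlap = np.intersect1d(oc, scd)
    tipd = geometry.tip_distance()
    return DomainLabeling(
        time=time,
        oc_cells=oc,
        scd_cells=scd,
        oc_count=int(oc.size),
        scd_count=int(scd.size),
        oc_components=_components(oc, geometry),
        scd_components=_components(scd, geometry),
        oc_centroid=(geometry.centres[oc].mean(axis=0)
                     if oc.size else None),
        scd_centroid=(geometry.centres[scd].mean(axis=0)
                      if scd.size else None),
        oc_tip_distance=(float(tipd[oc].mean()) if oc.size else float("nan")),
        scd_tip_distance=(float(tipd[scd].mean())
                          if scd.size else float("nan")),
        overlap_cells=overlap,
        adjacency_flag=(overlap.size == 0 and _touching(oc, scd, geometry)),
        wus_total=float(state[WUS].sum()),
        stemness_total=float(state[STEMNESS].sum()),
        tip_in_oc=bool(geometry.tip_cell in set(oc.tolist())),
    )


def summarize_sweep(knob_values: Sequence[float],
                    labelings: Sequence[DomainLabeling]) -> pd.DataFrame:
    """Response table of one labeling per sweep point.

    Attaches simple diagnostics: whether the OC count is constant over the
    sweep and whether the SCD count is monotone (non-increasing or
    non-decreasing) in the knob.
    """
    if len(knob_values) != len(labelings):
        raise ValueError("one labeling per knob value required")
    df = pd.DataFrame({
        "knob": list(knob_values),
        "oc_count": [lab.oc_count for lab in labelings],
        "scd_count": [lab.scd_count for lab in labelings],
    }).sort_values("knob", ignore_index=True)
    oc = df["oc_count"].to_numpy()
    scd = df["scd_count"].to_numpy()
    df.attrs["oc_constant"] = bool(np.all(oc == oc[0])) if oc.size else True
    dd = np.diff(scd)
    df.attrs["scd_monotone"] = bool(np.all(dd <= 0) or np.all(dd >= 0))
    df.attrs["scd_nonincreasing"] = bool(np.all(dd <= 0))
    return df


# ----------------------------------------------------------------------
# Outcome descriptors
# ----------------------------------------------------------------------

@dataclass
class OutcomeReport:
    descriptor: dict
    passed: bool
    diagnostics: dict


def check_outcome(descriptor: dict,
                  labelings: Sequence[DomainLabeling]) -> OutcomeReport:
    """Evaluate a machine-checkable qualitative outcome on a run.

    ``descriptor`` is a dict with a ``kind`` key plus reference quantities
    (wild-type counts/totals) resolved when the scenario recipe was built.
    Supported kinds:

    ``wild_type_arrangement``
        one connected OC, one connected SCD, disjoint, graph-adjacent,
        SCD tip-ward of OC, WUS excluded from the tip cell.
    ``oc_expansion_tipward``
        OC count above the wild-type count, OC centroid strictly closer to
        the tip, SCD count above wild type.
    ``collapse_no_recovery``
        stemness and WUS totals both below ``collapse_bound`` (default 5%)
        of wild type at the end, and stemness never recovers above
        ``recovery_bound`` after first dropping below ``drop_bound``.
    ``collapse_recovery``
        stemness total first drops below ``drop_bound`` (default 20%) of
        wild type, then ends above ``recovery_bound`` (default 60%).
    ``smaller_nonempty``
        both domains non-empty but strictly smaller than wild type.
    ``coalescence``
        OC/SCD overlap fraction above ``overlap_bound`` (default 0.5) and
        the joint domain wider than the wild-type SCD.
    ``mild_derepression``
        both domains at least wild-type sized (weak receptor background:
        the effect is bounded below by wild type, above by full loss).
    ``regeneration``
        both domains non-empty at the end of the run.
    ``overproliferation``
        every competent cell in the SCD and the OC spanning a majority of
        all cells.
    ``patterned``
        one connected OC and one connected SCD, disjoint and adjacent
        (position unconstrained; used for the constant-anchoring variant).
    """
    if not labelings:
        return OutcomeReport(descriptor, False, {"reason": "no data"})
    kind = descriptor.get("kind")
    last = labelings[-1]
    diag: dict = {"kind": kind, "final_oc_count": last.oc_count,
                  "final_scd_count": last.scd_count}

    if kind == "wild_type_arrangement":
        ok = (last.oc_components == 1 and last.scd_components == 1
              and last.overlap_count == 0 and last.adjacency_flag
              and last.scd_tip_distance < last.oc_tip_distance
              and not last.tip_in_oc)
        diag.update(oc_components=last.oc_components,
                    scd_components=last.scd_components,
                    overlap=last.overlap_count,
                    adjacency=last.adjacency_flag,
                    scd_tip_distance=last.scd_tip_distance,
                    oc_tip_distance=last.oc_tip_distance,
                    tip_in_oc=last.tip_in_oc)
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "oc_expansion_tipward":
        ok = (last.oc_count > descriptor["wt_oc_count"]
              and last.oc_tip_distance < descriptor["wt_oc_tip_distance"]
              and last.scd_count > descriptor["wt_scd_count"])
        diag.update(wt_oc_count=descriptor["wt_oc_count"],
                    oc_tip_distance=last.oc_tip_distance,
                    wt_oc_tip_distance=descriptor["wt_oc_tip_distance"])
        return OutcomeReport(descriptor, bool(ok), diag)

    st_series = np.array([lab.stemness_total for lab in labelings])
    wt_st = descriptor.get("wt_stemness_total")

    if kind == "collapse_no_recovery":
        bound = descriptor.get("collapse_bound", 0.05)
        drop = descriptor.get("drop_bound", 0.20)
        rec = descriptor.get("recovery_bound", 0.60)
        wt_wus = descriptor["wt_wus_total"]
        dropped = st_series < drop * wt_st
        ok = (last.stemness_total < bound * wt_st
              and last.wus_total < bound * wt_wus
              and (not dropped.any()
                   or not np.any(st_series[np.argmax(dropped):]
                                 > rec * wt_st)))
        diag.update(final_st_frac=last.stemness_total / wt_st,
                    final_wus_frac=last.wus_total / wt_wus)
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "collapse_recovery":
        drop = descriptor.get("drop_bound", 0.20)
        rec = descriptor.get("recovery_bound", 0.60)
        dropped = st_series < drop * wt_st
        ok = (dropped.any()
              and last.stemness_total > rec * wt_st)
        diag.update(min_st_frac=float(st_series.min() / wt_st),
                    final_st_frac=last.stemness_total / wt_st)
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "smaller_nonempty":
        ok = (0 < last.oc_count < descriptor["wt_oc_count"]
              and 0 < last.scd_count < descriptor["wt_scd_count"])
        diag.update(wt_oc_count=descriptor["wt_oc_count"],
                    wt_scd_count=descriptor["wt_scd_count"])
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "coalescence":
        bound = descriptor.get("overlap_bound", 0.5)
        joint = np.union1d(last.oc_cells, last.scd_cells).size
        ok = (last.overlap_fraction() > bound
              and joint > descriptor["wt_scd_count"])
        diag.update(overlap_fraction=last.overlap_fraction(),
                    joint_count=int(joint),
                    wt_scd_count=descriptor["wt_scd_count"])
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "mild_derepression":
        ok = (last.oc_count >= descriptor["wt_oc_count"] > 0
              and last.scd_count >= descriptor["wt_scd_count"] > 0)
        diag.update(wt_oc_count=descriptor["wt_oc_count"],
                    wt_scd_count=descriptor["wt_scd_count"])
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "regeneration":
        ok = last.oc_count > 0 and last.scd_count > 0
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "overproliferation":
        n_comp = descriptor["n_competent"]
        n_cells = descriptor["n_cells"]
        ok = (last.scd_count == n_comp and last.oc_count > n_cells / 2)
        diag.update(n_competent=n_comp, n_cells=n_cells)
        return OutcomeReport(descriptor, bool(ok), diag)

    if kind == "patterned":
        ok = (last.oc_components == 1 and last.scd_components == 1
              and last.overlap_count == 0 and last.adjacency_flag)
        diag.update(oc_components=last.oc_components,
                    scd_components=last.scd_components,
                    adjacency=last.adjacency_flag)
        return OutcomeReport(descriptor, bool(ok), diag)

    raise ValueError(f"unknown outcome descriptor kind {kind!r}")
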
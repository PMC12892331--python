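"""Binary ligand-pose compatibility against site descriptors.

A ligand pose, encoded as ligand vectors (farthest-exit lengths in the same
indexed directions as the site), fits a pocket conformation when its envelope
lies inside the pocket envelope: on every ray the ligand should not extend
past the first protein surface.  Small protrusions are tolerated: up to a
fraction ``max_violation_fraction`` of the ligand-intersecting rays may
protrude, each by at most ``slack`` Å (defaults 10% and 1 Å).  Both conditions
are conjunctive — a single protrusion past the slack rejects the pose, as does
too many small protrusions.

Only rays that actually intersect the ligand count toward the denominator;
screening an ensemble applies the criterion to every frame's site descriptor
and reports which frames can accommodate the pose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptor import LigandDescriptor, SiteDescriptor

__all__ = ["FitResult", "pose_compatible", "screen_ensemble",
           "charge_complementarity", "UndefinedPoseError"]


class UndefinedPoseError(ValueError):
    """The ligand intersects none of the scaffold rays."""


@dataclass(frozen=True)
class FitResult:
    accept: bool
    n_violations: int
    n_considered: int
    max_protrusion: float  # Å; 0 when nothing protrudes


def pose_compatible(ligand: LigandDescriptor, site: SiteDescriptor,
                    max_violation_fraction: float = 0.10,
                    slack: float = 1.0) -> FitResult:
    """Accept/reject one ligand pose against one site conformation.

    A considered ray is one with ``ligand.hit_mask`` True; it is a violation
    when the ligand length exceeds the site length there.  Accept iff every
    violation protrudes by at most ``slack`` Å and the violating fraction is
    at most ``max_violation_fraction``.
    """
    if len(ligand.lengths) != len(site.lengths):
        raise ValueError("ligand and site descriptors must share a scaffold")
    considered = ligand.hit_mask
    n_considered = int(considered.sum())
    if n_considered == 0:
        raise UndefinedPoseError(
            f"ligand {ligand.ligand_id!r} intersects no scaffold ray")
    protrusion = ligand.lengths[considered] - site.lengths[considered]
    violations = protrusion > 0
    n_violations = int(violations.sum())
    max_protrusion = float(protrusion[violations].max()) if n_violations else 0.0
    accept = (max_protrusion <= slack
              and n_violations <= max_violation_fraction * n_considered)
    return FitResult(accept=accept, n_violations=n_violations,
                     n_considered=n_considered, max_protrusion=max_protrusion)


def screen_ensemble(ligand: LigandDescriptor, sites: Sequence[SiteDescriptor],
                    max_violation_fraction: float = 0.10,
                    slack: float = 1.0) -> tuple[int, pd.DataFrame]:
    """Count the conformations that can accommodate a ligand pose.

    Returns the number of accepted frames and a per-frame table
    (frame, structure_id, accept, n_violations, n_considered, max_protrusion).
    """
    rows = []
    for site in sites:
        r = pose_compatible(ligand, site, max_violation_fraction, slack)
        rows.append({"frame": site.frame_index, "structure_id": site.structure_id,
                     "accept": r.accept, "n_violations": r.n_violations,
                     "n_considered": r.n_considered,
                     "max_protrusion": r.max_protrusion})
    table = pd.DataFrame(rows)
    return int(table["accept"].sum()), table


def charge_complementarity(ligand: LigandDescriptor, site: SiteDescriptor
                           ) -> pd.DataFrame:
    """Diagnostic per-ray ligand/site charge pairs on ligand-intersecting rays.

    Complementary electrostatics show up as opposite-sign pairs; this is
    reported for inspection and does not enter the accept/reject decision.
    """
    idx = np.flatnonzero(ligand.hit_mask)
    return pd.DataFrame({
        "vector": idx,
        "ligand_charge": ligand.charges[idx],
        "site_charge": site.charges[idx],
        "product": ligand.charges[idx] * site.charges[idx],
    })
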
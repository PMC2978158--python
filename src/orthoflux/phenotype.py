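"""Knockout-vs-wild-type FVA comparison and the subsystem shift statistic.

After a gene knockout, each reaction's flux capacity (its FVA maximum
v_max) either decreases, stays unchanged, or increases relative to the
wild type. Within each major metabolic subsystem the numbers of
decreased (n_down) and increased (n_up) reactions are compared against
an even split with a single-value chi-square test on 1 degree of
freedom:

    E = (n_down + n_up) / 2
    X^2 = (n_down - E)^2 / E + (n_up - E)^2 / E,   p = P(chi2_1 >= X^2)

with no continuity correction. Because one test is run per major
subsystem, significance is declared at the Bonferroni level alpha/k
(default 0.05/10). By convention, tallies of "significantly shifted
subsections of metabolism" exclude the Transporters subsystem, which is
not a metabolic subsection.

Also here: binary reaction-activity profiles from FVA and the
agglomerative tree over models built from them (Jaccard distance on the
active sets, average linkage, newick output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2

from .flux import FVAResult, delete_gene, run_fva
from .model import MediumCondition, MetabolicModel, ModelError, apply_medium

#: Relative tolerance / absolute floor below which a v_max change is noise.
REL_TOLERANCE = 1e-6
ABS_TOLERANCE = 1e-9

#: Default multiplicity: alpha over the number of major subsystems tested.
DEFAULT_ALPHA = 0.05
DEFAULT_N_TESTS = 10

#: The ten major subsystem labels used for the shift statistic.
MAJOR_SUBSYSTEMS = (
    "Amino Acid Metabolism",
    "Carbohydrate Metabolism",
    "Cofactor and Vitamin Metabolism",
    "Energy Metabolism",
    "Glycan Metabolism",
    "Lipid Metabolism",
    "Nucleotide Metabolism",
    "Other Amino Acids Metabolism",
    "Secondary Metabolites Metabolism",
    "Transporters",
)


@dataclass
class FluxCapacityChange:
    reaction_id: str
    status: str  # decreased | unchanged | increased
    delta_v_max: float


@dataclass
class SubsystemShiftTest:
    subsystem: str
    n_down: int
    n_up: int
    statistic: float
    p_value: float
    significant: bool


@dataclass
class ActivityProfile:
    """Binary activity vector of one model over a shared reaction universe."""

    label: str
    active: frozenset[str]


def compare_fva(
    wt: FVAResult,
    ko: FVAResult,
    rel_tol: float = REL_TOLERANCE,
    abs_tol: float = ABS_TOLERANCE,
) -> list[FluxCapacityChange]:
    """Classify each reaction's capacity change from the wild-type and
    knockout FVA maxima. Both results must cover the same reactions
    (knockout-disabled reactions appear with range (0, 0))."""
    if set(wt.ranges) != set(ko.ranges):
        raise ModelError("FVA results cover different reaction universes")
    changes = []
    for rid in wt.ranges:
        w = wt.ranges[rid][1]
        k = ko.ranges[rid][1]
        delta = k - w
        tol = max(abs_tol, rel_tol * max(abs(w), abs(k)))
        if delta < -tol:
            status = "decreased"
        elif delta > tol:
            status = "increased"
        else:
            status = "unchanged"
        changes.append(FluxCapacityChange(rid, status, delta))
    return changes


def chi_square_even(n_down: int, n_up: int) -> tuple[float, float]:
    """Chi-square (1 df) of an observed down/up split against even odds.

    Returns (statistic, upper-tail p). Zero total observations give
    (0, 1). No continuity correction is applied.
    """
    if n_down < 0 or n_up < 0:
        raise ValueError("counts must be non-negative")
    total = n_down + n_up
    if total == 0:
        return 0.0, 1.0
    expected = total / 2.0
    stat = (n_down - expected) ** 2 / expected + (n_up - expected) ** 2 / expected
    return float(stat), float(chi2.sf(stat, df=1))


def subsystem_shift_test(
    changes: list[FluxCapacityChange],
    subsystem_map: dict[str, str],
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_N_TESTS,
) -> list[SubsystemShiftTest]:
    """Per-subsystem chi-square shift tests at Bonferroni level alpha/k.

    ``subsystem_map`` sends reaction ids to major subsystem labels;
    unmapped or "unassigned" reactions are excluded, as are reactions
    with unchanged capacity.
    """
    counts: dict[str, list[int]] = {}
    for ch in changes:
        sub = subsystem_map.get(ch.reaction_id, "")
        if not sub or sub.lower() == "unassigned":
            continue
        counts.setdefault(sub, [0, 0])
        if ch.status == "decreased":
            counts[sub][0] += 1
        elif ch.status == "increased":
            counts[sub][1] += 1
    threshold = alpha / k
    out = []
    for sub in sorted(counts):
        down, up = counts[sub]
        stat, p = chi_square_even(down, up)
        out.append(SubsystemShiftTest(sub, down, up, stat, p, p < threshold))
    return out


def count_significant_metabolism(tests: list[SubsystemShiftTest]) -> int:
    """Significantly shifted subsections of metabolism proper: the
    Transporters subsystem is excluded from this tally."""
    return sum(t.significant for t in tests if t.subsystem != "Transporters")


def knockout_phenotype(
    model: MetabolicModel,
    medium: MediumCondition | None,
    gene: str,
    fraction: float = 1.0,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_N_TESTS,
) -> tuple[list[FluxCapacityChange], list[SubsystemShiftTest]]:
    """Full knockout analysis: FVA of wild type and knockout under the
    medium, capacity-change classification, per-subsystem shift tests."""
    base = apply_medium(model, medium) if medium is not None else model
    wt_fva = run_fva(base, fraction=fraction)
    ko = delete_gene(base, gene)
    ko_fva = run_fva(ko, fraction=fraction)
    changes = compare_fva(wt_fva, ko_fva)
    submap = {rid: r.subsystem for rid, r in base.reactions.items()}
    tests = subsystem_shift_test(changes, submap, alpha=alpha, k=k)
    return changes, tests


# ---------------------------------------------------------------------------
# FVA activity profiles and distance trees
# ---------------------------------------------------------------------------

def activity_profile(
    label: str, fva: FVAResult, tol: float = 1e-6
) -> ActivityProfile:
    return ActivityProfile(label, frozenset(fva.active_ids(tol)))


def fva_distance_tree(profiles: list[ActivityProfile]) -> str:
    """Average-linkage tree over models from Jaccard distances between
    their active-reaction sets; returns a newick string with branch
    lengths. Profiles are ordered by label for deterministic tie-breaks."""
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for a tree")
    labels = sorted(p.label for p in profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("profile labels must be unique")
    by_label = {p.label: p for p in profiles}
    ordered = [by_label[lab] for lab in labels]
    universe = sorted(set().union(*(p.active for p in ordered)))
    n = len(ordered)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ordered[i].active, ordered[j].active
            union = len(a | b)
            d = 0.0 if union == 0 else 1.0 - len(a & b) / union
            D[i, j] = D[j, i] = d
    Z = linkage(squareform(D, checks=False), method="average")
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(Z, labels)
    return str(tree).strip()
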
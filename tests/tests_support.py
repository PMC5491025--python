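"""Shared brute-force oracles for the test suite."""

import math

import numpy as np

from sbcc import CohortDesign, PopulationStructure


def brute_force_cgr(design, structure, subject_subpop, subject_in_cases, in_cohort, p):
    """Pairwise assembly of Cor(G, p_hat) at an explicit ancestral frequency.

    Enumerates every cohort member and sums the genotype variance/covariance
    of each pair — an O(n^2) path independent of the vectorized moments.
    """
    F = structure.fixation
    members = []  # (subpop, weight)
    n, n_ctrl = design.n_cases, design.n_controls
    for i in range(design.m):
        members += [(i, design.omega / (2 * n))] * design.cases_per_subpop[i]
        if design.omega < 1:
            members += [(i, (1 - design.omega) / (2 * n_ctrl))] * design.controls_per_subpop[i]

    def cov(i, j, same_subject):
        if same_subject:
            return 2 * p * (1 - p) * (1 + F[i])
        if i == j:
            return 4 * p * (1 - p) * F[i]
        return 0.0

    var_phat = sum(
        wa * wb * cov(ia, ib, a == b)
        for a, (ia, wa) in enumerate(members)
        for b, (ib, wb) in enumerate(members)
    )
    subject_id = None
    if in_cohort:
        target_weight = (
            design.omega / (2 * n) if subject_in_cases else (1 - design.omega) / (2 * n_ctrl)
        )
        for a, (ia, wa) in enumerate(members):
            if ia == subject_subpop and wa == target_weight:
                subject_id = a
                break
    cov_g_phat = sum(
        w * cov(subject_subpop, i, a == subject_id) for a, (i, w) in enumerate(members)
    )
    var_g = 2 * p * (1 - p) * (1 + F[subject_subpop])
    return cov_g_phat / math.sqrt(var_g * var_phat)


def brute_force_p_dependence():
    """Spread of the pairwise-oracle correlation across ancestral frequencies.

    Returns the max absolute difference over a p-grid for a deliberately
    lopsided design; the closed form requires this to vanish.
    """
    design = CohortDesign(np.array([8, 3, 14]), np.array([5, 9, 2]), omega=0.6)
    structure = PopulationStructure(np.array([0.01, 0.002, 0.05]))
    vals = [
        brute_force_cgr(design, structure, 0, True, True, p)
        for p in (0.05, 0.2, 0.5, 0.8, 0.95)
    ]
    return max(vals) - min(vals)
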
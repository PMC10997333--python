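"""Corpus-ratio lexical constraints and their interpretative-coherence indices.

For each target sentence the subject noun's thematic-role preference and
the first verb's subcategorization preference are summarised as ratios of
corpus counts:

* agenthood   = #agent-role uses / #patient-role uses (patienthood its
  reciprocal);
* transitivity = #direct-object frames / #alternative frames
  (intransitivity its reciprocal).

Their products quantify interpretative coherence: the *passive index*
patienthood x transitivity, the *active index* agenthood x intransitivity,
and a *non-directional index* log(agenthood) x log(intransitivity) which
measures coherence magnitude irrespective of which reading is favoured.
Continuation pre-tests provide contextualised analogues from the
probability of a direct-object continuation after the first verb and of a
main-verb continuation after the prepositional phrase.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

RATIO_COLUMNS = ("agenthood", "patienthood", "transitivity", "intransitivity")
INDEX_COLUMNS = ("passive_index", "active_index", "nondirectional_index")


def ratio_measures(counts: pd.DataFrame, smoothing: float = 0.0) -> pd.DataFrame:
    """Derive the four corpus-ratio measures from raw count columns.

    ``counts`` must have columns agent_count, patient_count, do_count,
    other_scf_count (one row per sentence).  With smoothing ``s``,
    agenthood = (agent + s) / (patient + s) and transitivity =
    (do + s) / (other + s); the reciprocals give patienthood and
    intransitivity.  Zero denominators with ``s = 0`` are an error.
    """
    required = ("agent_count", "patient_count", "do_count", "other_scf_count")
    missing = [c for c in required if c not in counts.columns]
    if missing:
        raise ValueError(f"missing count columns: {missing}")
    c = counts[list(required)].to_numpy(dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    s = float(smoothing)
    num = c + s
    if np.any(num == 0):
        bad = counts.index[np.any(num == 0, axis=1)].tolist()
        raise ValueError(
            f"zero counts with smoothing 0 make ratios undefined (rows {bad})"
        )
    out = counts.copy()
    out["agenthood"] = num[:, 0] / num[:, 1]
    out["patienthood"] = num[:, 1] / num[:, 0]
    out["transitivity"] = num[:, 2] / num[:, 3]
    out["intransitivity"] = num[:, 3] / num[:, 2]
    return out


def interpretation_indices(table: pd.DataFrame) -> pd.DataFrame:
    """Passive, active and non-directional coherence indices.

    passive = patienthood x transitivity; active = agenthood x
    intransitivity; non-directional = log(agenthood) x log(intransitivity)
    (log before multiplying removes the directionality: jointly swapping
    each ratio for its reciprocal leaves it unchanged, up to the identity
    log(agenthood)·log(intransitivity) = log(patienthood)·log(transitivity)).
    """
    missing = [c for c in RATIO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"ratio measures not computed: {missing}")
    vals = table[list(RATIO_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("ratio measures must be finite and positive")
    out = table.copy()
    out["passive_index"] = out["patienthood"] * out["transitivity"]
    out["active_index"] = out["agenthood"] * out["intransitivity"]
    out["nondirectional_index"] = np.log(out["agenthood"]) * np.log(
        out["intransitivity"]
    )
    return out


def continuation_probabilities(
    raw: pd.DataFrame, *, epsilon: float = 1e-3
) -> pd.DataFrame:
    """Continuation probabilities and contextualised (in)transitivity.

    ``raw`` has one row per (sentence_id, gate) with gate in
    {afterV1, afterPP} and columns n_responses, n_direct_object,
    n_prepositional_phrase, n_main_verb.  At the afterV1 gate,
    DO_prob = n_direct_object / n_responses and contextual transitivity =
    DO_prob / (1 − DO_prob); at the afterPP gate, MV_prob is analogous.
    DO_prob of exactly 0 or 1 is clipped to [eps, 1−eps] with a warning so
    the contextual ratios stay finite.
    """
    required = ("sentence_id", "gate", "n_responses", "n_direct_object",
                "n_prepositional_phrase", "n_main_verb")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"missing continuation columns: {missing}")
    cats = raw[["n_direct_object", "n_prepositional_phrase", "n_main_verb"]]
    if (cats.to_numpy() > raw["n_responses"].to_numpy()[:, None]).any():
        raise ValueError("category count exceeds n_responses")
    out = raw.copy()
    n = out["n_responses"].to_numpy(dtype=float)
    out["DO_prob"] = out["n_direct_object"] / n
    out["PP_prob"] = out["n_prepositional_phrase"] / n
    out["MV_prob"] = out["n_main_verb"] / n
    at_v1 = out["gate"] == "afterV1"
    p = out.loc[at_v1, "DO_prob"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "DO probability of 0 or 1 clipped for contextual transitivity"
        )
        p = np.clip(p, epsilon, 1 - epsilon)
    out.loc[at_v1, "contextual_transitivity"] = p / (1 - p)
    out.loc[at_v1, "contextual_intransitivity"] = (1 - p) / p
    return out


def permutation_spearman(
    x: Sequence[float],
    y: Sequence[float],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Spearman rho with a permutation p-value (add-one estimator).

    ``y`` is permuted; p = (1 + #{|rho_perm| >= |rho|}) / (n_perm + 1)
    for the two-sided default, with the obvious one-sided variants.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise ValueError("x and y must be equal-length 1-D with n >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: Spearman rho undefined")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(seed)
    perm_rho = np.empty(n_perm)
    rxc = rx - rx.mean()
    denom = np.sqrt(np.sum(rxc ** 2))
    for i in range(n_perm):
        ryp = ry[rng.permutation(y.size)]
        ryc = ryp - ryp.mean()
        perm_rho[i] = np.dot(rxc, ryc) / (denom * np.sqrt(np.sum(ryc ** 2)))
    if alternative == "two-sided":
        exceed = np.abs(perm_rho) >= abs(rho) - 1e-12
    elif alternative == "greater":
        exceed = perm_rho >= rho - 1e-12
    elif alternative == "less":
        exceed = perm_rho <= rho + 1e-12
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(exceed.sum())) / (n_perm + 1)
    return rho, float(p)


def fdr_correct(
    pvals: Sequence[float], alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (significance flags, adjusted p-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def summary_two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics alone."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float((mean1 - mean2) / se), int(df)


def correlation_report(
    measures: pd.DataFrame,
    target: Sequence[float],
    *,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation Spearman of every measure column against a target,
    FDR-corrected across measures; one row per measure."""
    rows = []
    for i, col in enumerate(measures.columns):
        rho, p = permutation_spearman(
            measures[col].to_numpy(), np.asarray(target, dtype=float),
            n_perm=n_perm, seed=seed + i,
        )
        rows.append({"variable": col, "rho": rho, "p": p})
    report = pd.DataFrame(rows)
    reject, p_adj = fdr_correct(report["p"].to_numpy(), alpha=alpha)
    report["p_fdr"] = p_adj
    report["significant"] = reject
    return report
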
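"""Candidate enumeration and BIC model selection (dredge-style).

All subsets of the global model's main effects and interactions are
enumerated under marginality (an interaction appears only with both main
effects present), fitted by maximum likelihood on an identical record set,
and ranked by BIC; the winner is refit by REML.
"""

from __future__ import annotations

import itertools
import warnings

import pandas as pd

from .lmm import ModelFit, ModelSpec, fit_lmm


def enumerate_candidates(global_spec: ModelSpec | None = None) -> list[ModelSpec]:
    """All marginality-respecting sub-models of ``global_spec``.

    Deterministic order: main subsets in binary counting order over the
    canonical term order, interactions likewise within each main subset.
    """
    if global_spec is None:
        global_spec = ModelSpec.global_model()
    mains = global_spec.mains
    inters = global_spec.interactions
    out: list[ModelSpec] = []
    for r in range(len(mains) + 1):
        for msub in itertools.combinations(mains, r):
            valid = [p for p in inters if p[0] in msub and p[1] in msub]
            for q in range(len(valid) + 1):
                for isub in itertools.combinations(valid, q):
                    out.append(ModelSpec(mains=msub, interactions=isub,
                                         reml=False))
    return out


def select_by_bic(table: pd.DataFrame,
                  candidates: list[ModelSpec]) -> tuple[ModelFit, pd.DataFrame]:
    """ML-fit every candidate, rank by BIC, REML-refit the winner.

    Ties break toward fewer parameters, then lexicographic term order.
    Candidates that fail to fit are dropped with a warning. Returns the
    REML refit of the best model and the full ranking table.
    """
    if not candidates:
        raise ValueError("no candidate models given")
    rows = []
    for spec in candidates:
        try:
            fit = fit_lmm(table, spec)
        except Exception as exc:  # noqa: BLE001 - candidate-level robustness
            warnings.warn(f"candidate {spec.key()!r} dropped: {exc}",
                          stacklevel=2)
            continue
        rows.append({"model": spec.key(), "spec": spec, "bic": fit.bic,
                     "k": fit.k_params, "llf": fit.llf,
                     "converged": fit.converged})
    if not rows:
        raise RuntimeError("every candidate model failed to fit")
    ranking = pd.DataFrame(rows).sort_values(
        by=["bic", "k", "model"], kind="mergesort").reset_index(drop=True)
    best_spec: ModelSpec = ranking.loc[0, "spec"]
    final = fit_lmm(table, ModelSpec(mains=best_spec.mains,
                                     interactions=best_spec.interactions,
                                     reml=True,
                                     allow_nonmarginal=best_spec.allow_nonmarginal))
    return final, ranking.drop(columns="spec").assign(
        rank=lambda d: d.index + 1)
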
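"""Independent brute-force oracles for the MILP-based solvers.

Deliberately naive: exhaustive enumeration of Boolean states plus one
scipy ``linprog`` call per state, with no shared code with the package's
MILP encodings. Only usable on small fixtures.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from geneforce import rules as rl
from geneforce.model import apply_condition
from geneforce.rules import SymbolKind

EPS_FLUX = 1e-4


def _lp_max_growth(bounded, gene_truth, flux_pred_truth=None):
    """Max biomass flux with reactions closed when their GPR is false under
    ``gene_truth``; flux-predicate truths add v>=eps / v<=0 side bounds."""
    rxns = list(bounded.reactions.values())
    index = {r.id: i for i, r in enumerate(rxns)}
    lb = np.array([r.lb for r in rxns], dtype=float)
    ub = np.array([r.ub for r in rxns], dtype=float)
    for i, r in enumerate(rxns):
        if r.gpr is not None:
            a = {g: gene_truth.get(g, True) for g in r.gpr_genes()}
            if not rl.evaluate(r.gpr, a):
                lb[i] = ub[i] = 0.0
    for key, truth in (flux_pred_truth or {}).items():
        name, tau = key.rsplit(">", 1)
        i = index[name if name != "Growth" else bounded.biomass_id]
        if truth:
            lb[i] = max(lb[i], float(tau) + EPS_FLUX)
        else:
            ub[i] = min(ub[i], float(tau))
    if np.any(lb > ub):
        return None
    mets = sorted({m for r in rxns for m in r.stoich})
    s = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(rxns):
        for m, c in r.stoich.items():
            s[mets.index(m), j] += c
    c_vec = np.zeros(len(rxns))
    c_vec[index[bounded.biomass_id]] = -1.0
    res = linprog(c_vec, A_eq=s, b_eq=np.zeros(len(mets)),
                  bounds=list(zip(lb, ub)), method="highs")
    return -res.fun if res.status == 0 else None


def fba_max(model, condition, knockouts=()):
    bounded, _ = apply_condition(model, condition)
    truth = {g: g not in set(knockouts) for g in bounded.genes}
    mu = _lp_max_growth(bounded, truth)
    return 0.0 if mu is None else mu


def enumerate_consistent_states(model, condition, knockouts=()):
    """Yield every (gene_truth, tf_truth, flux_pred_truth) assignment that
    satisfies all rules under the condition's environmental truths."""
    bounded, env_truth = apply_condition(model, condition)
    reg = model.regulatory
    knockouts = set(knockouts)
    genes = sorted(bounded.genes | set(reg.gene_rules))
    tfs = sorted(reg.tfs)
    fps = sorted({s.key for s in model.flux_predicates()})
    free = [g for g in genes if g not in knockouts]
    free_tfs = [t for t in tfs if t not in knockouts]
    for bits in itertools.product([False, True],
                                  repeat=len(free) + len(free_tfs) + len(fps)):
        gene_truth = dict(zip(free, bits[: len(free)]))
        gene_truth.update({g: False for g in knockouts if g in genes})
        tf_truth = dict(zip(free_tfs, bits[len(free): len(free) + len(free_tfs)]))
        tf_truth.update({t: False for t in tfs if t in knockouts})
        fp_truth = dict(zip(fps, bits[len(free) + len(free_tfs):]))
        a = {**gene_truth, **tf_truth, **fp_truth, **env_truth}
        # deletion overrides transcription: deleted targets skip their rule
        ok = all(rl.evaluate(rule, a) == gene_truth[t]
                 for t, rule in reg.gene_rules.items() if t not in knockouts)
        ok = ok and all(rl.evaluate(rule, a) == tf_truth[t]
                        for t, rule in reg.tf_rules.items() if t not in knockouts)
        if ok:
            yield gene_truth, tf_truth, fp_truth


def srfba_max(model, condition, knockouts=()):
    """Max growth over all exhaustively enumerated consistent states."""
    bounded, _ = apply_condition(model, condition)
    best = 0.0
    for gene_truth, _, fp_truth in enumerate_consistent_states(
            model, condition, knockouts):
        mu = _lp_max_growth(bounded, gene_truth, fp_truth)
        if mu is not None and mu > best:
            best = mu
    return best


def geneforce_minimum(model, condition, knockouts=(), threshold_fraction=0.1,
                      max_size=None, tol=1e-7):
    """Smallest violation-set size and the full family of minimum sets.

    A set F is feasible iff some rule-consistent state has every gene of F
    unexpressed and the LP — with reactions gated as if F were expressed on
    top of that state — reaches the growth threshold.
    """
    knockouts = set(knockouts)
    mu_fba = fba_max(model, condition, knockouts)
    assert mu_fba > 1e-6, "not a violation-minimization case"
    threshold = threshold_fraction * mu_fba
    bounded, _ = apply_condition(model, condition)
    candidates = sorted(set(model.regulatory.gene_rules) - knockouts)
    states = list(enumerate_consistent_states(model, condition, knockouts))
    limit = len(candidates) if max_size is None else max_size
    for size in range(0, limit + 1):
        family = set()
        for subset in itertools.combinations(candidates, size):
            forced = set(subset)
            for gene_truth, _, fp_truth in states:
                if any(gene_truth[g] for g in forced):
                    continue  # violation only counts genes the rules keep off
                gated = dict(gene_truth)
                gated.update({g: True for g in forced})
                mu = _lp_max_growth(bounded, gated, fp_truth)
                if mu is not None and mu >= threshold - tol:
                    family.add(frozenset(forced))
                    break
        if family:
            return size, family
    raise AssertionError("threshold unreachable even with all rules violated")
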
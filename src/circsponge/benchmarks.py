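"""Self-contained validation benchmarks.

Each function builds its own synthetic inputs (or loads the packaged fixture
tables), runs the relevant pipeline stage, and returns measured quantities:
oracle agreement for seed matching and the hypergeometric test, type-I error
of the two-group t-test, recovery of planted differential effects, and
recovery of planted sponge triplets.  The acceptance tests and the
``scripts/acceptance.py`` reporter both call these.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np
from scipy import stats

from . import diffexp, preprocess, seedmatch, synthetic
from .cerna import build_triplets, pairwise_pearson
from .seedmatch import SEED_KINDS, SequenceRecord

__all__ = [
    "brute_force_seed_scan",
    "seedmatch_oracle_agreement",
    "hypergeom_exact_p",
    "hypergeom_subset_enumeration_p",
    "hypergeom_max_error",
    "type1_error_rate",
    "de_recovery",
    "cerna_recovery",
    "quantile_normalization_invariants",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_seed_scan(
    mirna: SequenceRecord, target: SequenceRecord, kinds=SEED_KINDS, circular: bool = True
) -> list[tuple[str, int, int]]:
    """Exhaustive substring-complementarity oracle, independent of the
    matcher: tests every start position of every site length directly.

    Returns (kind, start, end) tuples.
    """
    mi = mirna.sequence.upper().replace("U", "T")
    tg = target.sequence.upper().replace("U", "T")
    L = len(tg)
    wrap = circular and target.molecule_class == "circRNA"
    hits = []
    for kind in kinds:
        if kind in ("6mer", "7mer_A1"):
            seed = mi[1:7]
        else:
            seed = mi[1:8]
        # antisense: site read 5'->3' must be the reversed complement of the seed
        site = "".join(_COMP[b] for b in reversed(seed))
        if kind in ("7mer_A1", "8mer"):
            site = site + "A"
        k = len(site)
        extended = tg + tg[: k - 1] if (wrap and L >= k) else tg
        n_starts = L if (wrap and L >= k) else max(0, len(tg) - k + 1)
        for start in range(n_starts):
            if extended[start : start + k] == site:
                hits.append((kind, start, start + k))
    return sorted(hits, key=lambda h: (h[1], SEED_KINDS.index(h[0])))


def seedmatch_oracle_agreement(
    n_pairs: int = 100, target_length: int = 1000, seed: int = 0
) -> dict:
    """Fraction of random (miRNA, target) pairs where the matcher reproduces
    the brute-force scan exactly, over all four seed classes."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    agree = 0
    total_sites = 0
    for i in range(n_pairs):
        mi = SequenceRecord(
            f"m{i}", "miRNA", "".join(rng.choice(bases, size=int(rng.integers(18, 26))))
        )
        cls = "circRNA" if i % 2 == 0 else "mRNA_3utr"
        tg = SequenceRecord(
            f"t{i}", cls, "".join(rng.choice(bases, size=target_length))
        )
        found = [
            (s.seed_kind, s.start, s.end)
            for s in seedmatch.find_seed_matches(mi, tg, kinds=SEED_KINDS)
        ]
        expected = brute_force_seed_scan(mi, tg)
        total_sites += len(expected)
        if found == expected:
            agree += 1
    return {
        "agreement_fraction": agree / n_pairs,
        "n_pairs": n_pairs,
        "total_sites": total_sites,
    }


def hypergeom_exact_p(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper-tail P[X >= k] as a rational number (combinatorial sum)."""
    denom = math.comb(N, n)
    upper = min(n, K)
    num = sum(math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, upper + 1))
    return Fraction(num, denom)


def hypergeom_subset_enumeration_p(N: int, K: int, n: int, k: int) -> Fraction:
    """Literal enumeration over all n-subsets of an N-universe (tiny N only):
    the fraction of draws with at least k members of the K-set."""
    universe = range(N)
    in_k = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(in_k & set(draw)) >= k
    )
    return Fraction(hits, math.comb(N, n))


def hypergeom_max_error(max_N: int = 30) -> dict:
    """Max |scipy upper-tail - exact rational| over every configuration with
    N <= max_N, 1 <= k <= min(n, K)."""
    worst = 0.0
    count = 0
    for N in range(1, max_N + 1):
        for K in range(0, N + 1):
            for n in range(0, N + 1):
                lo = max(1, n + K - N)
                hi = min(n, K)
                if hi < lo:
                    continue
                ks = np.arange(lo, hi + 1)
                ps = stats.hypergeom.sf(ks - 1, N, K, n)
                for k, p in zip(ks, ps):
                    exact = float(hypergeom_exact_p(N, K, n, int(k)))
                    worst = max(worst, abs(float(p) - exact))
                    count += 1
    return {"max_abs_error": worst, "n_configurations": count}


def _log2_matrix(matrix) -> "preprocess.ExpressionMatrix":
    return preprocess.log2_transform(matrix, offset=0.0)


def type1_error_rate(
    n_probes: int = 10_000, alpha: float = 0.05, noise_sd: float = 0.25, seed: int = 0
) -> dict:
    """Rejection rate of the pooled 3-vs-3 t-test on purely null probes."""
    probes = [f"p{i}" for i in range(n_probes)]
    m, _ = synthetic.generate_expression(
        probes, de_plan=[], noise_sd=noise_sd, rng_seed=seed
    )
    logm = _log2_matrix(m)
    case, ctrl = logm.group_labels[1], logm.group_labels[0]
    pvals = diffexp.two_group_t_test(logm, case, ctrl, variant="pooled")
    rate = float((pvals["p_raw"] < alpha).mean())
    return {"rejection_rate": rate, "n_probes": n_probes}


def de_recovery(
    n_sims: int = 50,
    n_probes: int = 500,
    n_planted: int = 50,
    noise_sd: float = 0.25,
    fc_min: float = 2.0,
    p_max: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recall of planted >= 4-fold effects and false-call rate among null
    probes at the standard (fold >= 2, p < 0.05) selection."""
    rng = np.random.default_rng(seed)
    probes = [f"p{i}" for i in range(n_probes)]
    tp = fn = fp = tn = 0
    for _ in range(n_sims):
        folds = rng.uniform(4.0, 8.0, size=n_planted)
        directions = rng.choice(["up", "down"], size=n_planted)
        de_plan = [
            (probes[i], directions[i], float(folds[i])) for i in range(n_planted)
        ]
        m, truth = synthetic.generate_expression(
            probes, de_plan=de_plan, noise_sd=noise_sd,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        logm = preprocess.quantile_normalize(_log2_matrix(m))
        case, ctrl = logm.group_labels[1], logm.group_labels[0]
        fold = diffexp.fold_change_and_direction(logm, case, ctrl)
        pvals = diffexp.two_group_t_test(logm, case, ctrl)
        table = diffexp.select_differential(fold, pvals, fc_min=fc_min, p_max=p_max)
        called = set(table.records.index)
        planted = {p for p, _d, _f in truth.de_probes}
        tp += len(called & planted)
        fn += len(planted - called)
        fp += len(called - planted)
        tn += n_probes - n_planted - len(called - planted)
    return {
        "recall": tp / (tp + fn),
        "false_call_rate": fp / (fp + tn),
        "n_sims": n_sims,
    }


def cerna_recovery(
    n_sims: int = 20,
    n_planted: int = 20,
    n_decoys: int = 200,
    planted_r: float = 0.9,
    planted_fold: float = 4.0,
    noise_sd: float = 0.25,
    r_min: float = 0.9,
    r_p_max: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recovery of planted sponge triplets against site-sharing decoys.

    Planted triplets are injury-responsive pairs (both members differentially
    expressed at ``planted_fold``, alternating direction across triplets)
    sharing a miRNA 8mer site and a latent co-fluctuation of planned Pearson
    ``planted_r``.  Each decoy is a circRNA/mRNA pair sharing a miRNA seed
    site but with independent, non-differential expression.  The target map
    holds exactly the designed pair universe (planted + decoys): each
    designated miRNA-target pair is scanned for its real seed sites, so the
    number of correlation-screened pairs matches the stated decoy count.
    Recall and precision are aggregated over simulations against the truth
    table.
    """
    rng = np.random.default_rng(seed)
    n_pairs = n_planted + n_decoys
    tp = fn = fp = 0
    for _ in range(n_sims):
        site_plan = []
        for i in range(n_pairs):
            site_plan.append((f"miR{i+1}", f"circ{i+1}", 1))
            site_plan.append((f"miR{i+1}", f"utr{i+1}", 1))
        seqs, _ = synthetic.generate_sequences(
            n_mirna=n_pairs, n_circ=n_pairs, n_mrna=n_pairs,
            site_plan=site_plan, rng_seed=int(rng.integers(0, 2**31 - 1)),
            circ_length=120, mrna_length=120, seed_kind="8mer",
        )
        by_id = {s.id: s for s in seqs}
        target_map = {}
        for i in range(n_pairs):
            mi = by_id[f"miR{i+1}"]
            target_map[mi.id] = {
                t.id: seedmatch.find_seed_matches(mi, t, kinds=("8mer",))
                for t in (by_id[f"circ{i+1}"], by_id[f"utr{i+1}"])
            }

        probes = [f"circ{i+1}" for i in range(n_pairs)] + [
            f"utr{i+1}" for i in range(n_pairs)
        ]
        de_plan = []
        triplet_plan = []
        truth_triplets = set()
        for i in range(n_planted):
            d = "up" if i % 2 == 0 else "down"
            de_plan += [(f"circ{i+1}", d, planted_fold), (f"utr{i+1}", d, planted_fold)]
            triplet_plan.append((f"circ{i+1}", f"utr{i+1}", planted_r))
            truth_triplets.add((f"circ{i+1}", f"miR{i+1}", f"utr{i+1}"))
        m, _ = synthetic.generate_expression(
            probes, de_plan=de_plan, triplet_plan=triplet_plan,
            noise_sd=noise_sd, rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        logm = _log2_matrix(m)
        circ_expr = logm.with_values(logm.values.loc[[p for p in probes if p.startswith("circ")]])
        mrna_expr = logm.with_values(logm.values.loc[[p for p in probes if p.startswith("utr")]])
        corr = pairwise_pearson(circ_expr, mrna_expr)
        triplets = build_triplets(target_map, corr, r_min=r_min, r_p_max=r_p_max)
        found = {(t.circ_id, t.mirna_id, t.mrna_id) for t in triplets}
        tp += len(found & truth_triplets)
        fn += len(truth_triplets - found)
        fp += len(found - truth_triplets)
    return {
        "recall": tp / (tp + fn),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "n_sims": n_sims,
    }


def quantile_normalization_invariants(
    n_probes: int = 400, n_samples: int = 6, seed: int = 0
) -> dict:
    """Post-normalization column-distribution identity and idempotence."""
    rng = np.random.default_rng(seed)
    import pandas as pd

    from .matrix import ExpressionMatrix

    values = pd.DataFrame(
        rng.normal(8, 2, size=(n_probes, n_samples)),
        index=[f"p{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    groups = {f"s{j}": ("a" if j < n_samples // 2 else "b") for j in range(n_samples)}
    m = ExpressionMatrix(values=values, scale="log2", groups=groups)
    once = preprocess.quantile_normalize(m)
    X = once.values.to_numpy()
    sorted_cols = np.sort(X, axis=0)
    dist_dev = float(np.max(np.abs(sorted_cols - sorted_cols[:, [0]])))
    twice = preprocess.quantile_normalize(once)
    idem_dev = float(np.max(np.abs(twice.values.to_numpy() - X)))
    return {
        "column_distribution_max_dev": dist_dev,
        "idempotence_max_dev": idem_dev,
        "n_probes": n_probes,
    }
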
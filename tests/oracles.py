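"""Independent brute-force references used only by the test suite.

These deliberately re-derive everything from first principles (repeated set
expansion, exhaustive pair counting, O(n^2) concordance) so they share no
code with the package implementation.
"""

from __future__ import annotations

import numpy as np


def brute_force_clonality(cells):
    """Exhaustive reference partition of one donor's cells.

    Returns a dict cell_id -> label string among main_clone /
    related_to_main_clone / bystander_group / single_bystander.
    """
    # exhaustive dominant pair count
    pair_counts = {}
    alpha_support = {}
    beta_support = {}
    for c in cells:
        for a in c.alpha_set:
            alpha_support[a] = alpha_support.get(a, 0) + 1
        for b in c.beta_set:
            beta_support[b] = beta_support.get(b, 0) + 1
        for a in c.alpha_set:
            for b in c.beta_set:
                pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    labels = {}
    if pair_counts:
        best = None
        for pair, count in pair_counts.items():
            support = alpha_support[pair[0]] + beta_support[pair[1]]
            key = (-count, -support, pair[0], pair[1])
            if best is None or key < best[0]:
                best = (key, pair)
        a1, b1 = best[1]
        # component by repeated set expansion over cells
        component = {a1, b1}
        changed = True
        while changed:
            changed = False
            for c in cells:
                chains = set(c.alpha_set) | set(c.beta_set)
                if chains & component and not chains <= component:
                    component |= chains
                    changed = True
        for c in cells:
            if a1 in c.alpha_set or b1 in c.beta_set:
                labels[c.cell_id] = "main_clone"
            elif (set(c.alpha_set) | set(c.beta_set)) & component:
                labels[c.cell_id] = "related_to_main_clone"
    remaining = [c for c in cells if c.cell_id not in labels]
    for c in remaining:
        same = [
            o
            for o in remaining
            if set(o.alpha_set) == set(c.alpha_set) and set(o.beta_set) == set(c.beta_set)
        ]
        labels[c.cell_id] = "bystander_group" if len(same) >= 2 else "single_bystander"
    return labels


def pairwise_auc(scores, targets):
    """O(n^2) concordance probability; ties count one half."""
    scores = np.asarray(scores, dtype=float)
    targets = np.asarray(targets)
    pos = scores[targets == 1]
    neg = scores[targets == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypernet_reference(params, x):
    """Direct scalar-loop evaluation of the two displayed model equations."""
    W_A, b_A = params.W_A, params.bias_A
    W_B, b_B = params.W_B, params.bias_B
    W_C, b_C = params.W_C, params.bias_C
    H, G = W_A.shape

    h1 = [np.tanh(b_A[i] + sum(W_A[i, g] * x[g] for g in range(G))) for i in range(H)]
    h2 = [np.tanh(b_B[i] + sum(W_B[i, j] * h1[j] for j in range(H))) for i in range(H)]
    u = [1.0 / (1.0 + np.exp(-(b_C[g] + sum(W_C[g, j] * h2[j] for j in range(H)))))
         for g in range(G)]
    exps = [np.exp(v) for v in u]
    total = sum(exps)
    a = [e / total for e in exps]
    z = params.bias_D + params.w_D * sum(a[g] * x[g] for g in range(G))
    p = 1.0 / (1.0 + np.exp(-z))
    return np.array(a), p


def selu_reference(params, widths, x):
    """Layer-by-layer SELU network evaluation with explicit loops."""
    alpha, scale = 1.6732632423543772, 1.0507009873554805
    a = list(x)
    n_layers = len(widths) + 1
    for i in range(n_layers):
        W, b = params[f"W{i}"], params[f"b{i}"]
        z = [b[o] + sum(W[o, j] * a[j] for j in range(len(a))) for o in range(W.shape[0])]
        if i < n_layers - 1:
            a = [scale * (v if v > 0 else alpha * (np.exp(v) - 1.0)) for v in z]
        else:
            a = [1.0 / (1.0 + np.exp(-v)) for v in z]
    return a[0]
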
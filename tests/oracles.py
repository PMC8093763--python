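"""Independent brute-force reference implementations used only by tests.

These deliberately take the slowest, most literal route (explicit loops,
pair counting, exhaustive enumeration) and never share code with the
package paths they check.
"""

import itertools

import numpy as np
from sklearn.metrics import cohen_kappa_score


def labels_from_cm(matrix):
    """Reconstruct (y_true, y_pred) label sequences from confusion counts."""
    y_true, y_pred = [], []
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            y_true.extend([i] * matrix[i, j])
            y_pred.extend([j] * matrix[i, j])
    return np.array(y_true), np.array(y_pred)


def kappa_oracle(matrix):
    y_true, y_pred = labels_from_cm(matrix)
    return cohen_kappa_score(y_true, y_pred, labels=list(range(matrix.shape[0])))


def gmean_oracle(matrix):
    recalls = []
    for i in range(matrix.shape[0]):
        row = matrix[i].sum()
        if row == 0:
            continue
        recalls.append(matrix[i, i] / row)
    prod = 1.0
    for r in recalls:
        prod *= r
    return prod ** (1.0 / len(recalls))


def pairwise_auc_oracle(scores_i, scores_j):
    """P(class-i sample outranks class-j sample), ties counted half."""
    wins = 0.0
    for a in scores_i:
        for b in scores_j:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(scores_i) * len(scores_j))


def mauc_oracle(classes, scores, y_true):
    present = [c for c in classes if np.any(y_true == c)]
    total, n_pairs = 0.0, 0
    for i in present:
        for j in present:
            if i == j:
                continue
            col = classes.index(i)
            s_i = scores[y_true == i, col]
            s_j = scores[y_true == j, col]
            total += pairwise_auc_oracle(s_i, s_j)
            n_pairs += 1
    return total / n_pairs


def footrule_oracle(ordering, list_ids, norm_weights):
    """Direct summed |rank difference| x weight."""
    d = 0.0
    for pos, c in enumerate(ordering):
        d += abs((pos + 1) - (list_ids.index(c) + 1)) * norm_weights[c]
    return d


def exhaustive_consensus(lists, list_weights, objective):
    """Global minimum of the aggregation objective over all permutations."""
    ids = sorted(lists[0].ids, key=str)
    best, best_obj = None, np.inf
    for perm in itertools.permutations(ids):
        obj = objective(list(perm), lists, list_weights)
        if obj < best_obj - 1e-12:
            best, best_obj = list(perm), obj
    return best, best_obj


def count_kmers_oracle(seq, k, canonical):
    """Quadratic, window-by-window enumeration with explicit N handling."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    counts = {}
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if any(ch not in comp for ch in window):
            continue
        if canonical:
            rc = "".join(comp[ch] for ch in reversed(window))
            window = min(window, rc)
        counts[window] = counts.get(window, 0) + 1
    return counts
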
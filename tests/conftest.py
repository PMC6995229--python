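"""Shared fixtures and independent oracles used across the test suite."""

import numpy as np
import pytest

from hspreg.io_formats import AlignedSequenceSet, Arrangement, SequenceRecord
from hspreg.popgen_diff import PopulationSplit


def make_alignment(seqs, arrangements=None, ids=None):
    """Build an AlignedSequenceSet from raw strings."""
    ids = ids or [f"s{i}" for i in range(len(seqs))]
    arrangements = arrangements or [Arrangement.OTHER] * len(seqs)
    return AlignedSequenceSet(
        tuple(
            SequenceRecord(id=i, sequence=s, arrangement=a)
            for i, s, a in zip(ids, seqs, arrangements)
        )
    )


def random_alignment(rng, n, length):
    """Random gap-free alignment of n sequences."""
    bases = np.array(list("ACGT"))
    seqs = ["".join(rng.choice(bases, size=length)) for _ in range(n)]
    return make_alignment(seqs)


def two_pop_split(aln, n1):
    ids = aln.ids
    return PopulationSplit(ids[:n1], ids[n1:])


# ---------------------------------------------------------------------------
# brute-force popgen oracles (explicit loops; no shared code with hspreg)
# ---------------------------------------------------------------------------


def oracle_hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def oracle_dxy(seqs1, seqs2):
    L = len(seqs1[0])
    total = 0
    for a in seqs1:
        for b in seqs2:
            total += oracle_hamming(a, b)
    return total / (len(seqs1) * len(seqs2) * L)


def oracle_within(seqs):
    L = len(seqs[0])
    pairs = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            pairs.append(oracle_hamming(seqs[i], seqs[j]))
    return sum(pairs) / (len(pairs) * L)


def oracle_fst(seqs1, seqs2):
    hw = (oracle_within(seqs1) + oracle_within(seqs2)) / 2
    hb = oracle_dxy(seqs1, seqs2)
    return 1 - hw / hb


def oracle_snn(seqs1, seqs2):
    seqs = list(seqs1) + list(seqs2)
    labels = [1] * len(seqs1) + [2] * len(seqs2)
    total = 0.0
    for i in range(len(seqs)):
        dists = [
            (oracle_hamming(seqs[i], seqs[j]), j)
            for j in range(len(seqs))
            if j != i
        ]
        m = min(d for d, _ in dists)
        nn = [j for d, j in dists if d == m]
        total += sum(labels[j] == labels[i] for j in nn) / len(nn)
    return total / len(seqs)


# ---------------------------------------------------------------------------
# brute-force HSE oracle: enumerate every (start, unit_count) window
# ---------------------------------------------------------------------------


def oracle_hse(seq, min_units=3):
    seq = seq.upper()

    def core(p):
        c = seq[p + 1 : p + 4]
        if c == "GAA":
            return "G"
        if c == "TTC":
            return "T"
        return None

    def valid(start, k):
        if start < 0 or start + 5 * k > len(seq):
            return False
        types = [core(start + 5 * u) for u in range(k)]
        if any(t is None for t in types):
            return False
        return all(types[u] != types[u + 1] for u in range(k - 1))

    hits = []
    for start in range(len(seq)):
        for k in range(min_units, len(seq) // 5 + 1):
            if not valid(start, k):
                continue
            extendable = valid(start - 5, k + 1) or valid(start, k + 1)
            if not extendable:
                hits.append((start, start + 5 * k, k))
    return sorted(set(hits))


# ---------------------------------------------------------------------------
# balanced nested-ANOVA closed-form oracle (cell-mean formulas)
# ---------------------------------------------------------------------------


def oracle_balanced_anova(y, arr, line, sex):
    """Sums of squares for a balanced 2 x lines x 2 x reps nested design."""
    y = np.asarray(y, dtype=float)
    arr = np.asarray(arr)
    line = np.asarray(line)
    sex = np.asarray(sex)
    grand = y.mean()
    ss_arr = sum(
        (y[arr == a]).size * (y[arr == a].mean() - grand) ** 2 for a in np.unique(arr)
    )
    ss_line = 0.0
    for a in np.unique(arr):
        mu_a = y[arr == a].mean()
        for l in np.unique(line[arr == a]):
            sel = (arr == a) & (line == l)
            ss_line += sel.sum() * (y[sel].mean() - mu_a) ** 2
    ss_sex = sum(
        (y[sex == s]).size * (y[sex == s].mean() - grand) ** 2 for s in np.unique(sex)
    )
    ss_int = 0.0
    for a in np.unique(arr):
        for s in np.unique(sex):
            sel = (arr == a) & (sex == s)
            ss_int += sel.sum() * (
                y[sel].mean() - y[arr == a].mean() - y[sex == s].mean() + grand
            ) ** 2
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_arr - ss_line - ss_sex - ss_int
    return {
        "arrangement": ss_arr,
        "line_within_arrangement": ss_line,
        "sex": ss_sex,
        "arrangement_by_sex": ss_int,
        "error": ss_err,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20200131)
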
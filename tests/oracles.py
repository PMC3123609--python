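"""Independent brute-force reference implementations used by the tests.

Everything here is written from the measure definitions with plain Python
dictionaries and explicit loops — no numpy, no code shared with the package —
so agreement between the two routes is meaningful.  The ``base`` argument
makes the log base explicit, which the tests use to check that normalized
scores are base-free.
"""

import math
from collections import Counter

GAP = "-"

TAYLOR = {
    "hydrophobic": set("AGCTIVLKHFYWM"),
    "aromatic": set("FYWH"),
    "aliphatic": set("IVL"),
    "tiny": set("ASGC"),
    "small": set("PNDTCAGSV"),
    "proline": set("P"),
    "charged": set("KHRDE"),
    "negative": set("DE"),
    "polar": set("NQSDECTKRHYW"),
    "positive": set("KHR"),
}


def _log(x, base):
    return math.log(x) / math.log(base)


def pair_rows(col_k, col_l):
    """Rows where both columns are non-gap."""
    return [(a, b) for a, b in zip(col_k, col_l) if a != GAP and b != GAP]


def column_entropy(column, base=math.e):
    column = [c for c in column if c != GAP]
    n = len(column)
    return -sum(c / n * _log(c / n, base) for c in Counter(column).values())


def joint_entropy(col_k, col_l, base=math.e):
    rows = pair_rows(col_k, col_l)
    n = len(rows)
    return -sum(c / n * _log(c / n, base) for c in Counter(rows).values())


def _marginals(rows):
    n = len(rows)
    pk = Counter(a for a, _ in rows)
    pl = Counter(b for _, b in rows)
    return (
        {a: c / n for a, c in pk.items()},
        {b: c / n for b, c in pl.items()},
        {ab: c / n for ab, c in Counter(rows).items()},
    )


def _modified(marg, background):
    ratio = {a: p / background[a] for a, p in marg.items()}
    total = sum(ratio.values())
    return {a: r / total for a, r in ratio.items()}


def mi_normalized(col_k, col_l, base=math.e):
    rows = pair_rows(col_k, col_l)
    pk, pl, joint = _marginals(rows)
    raw = sum(
        p * _log(p / (pk[a] * pl[b]), base) for (a, b), p in joint.items()
    )
    h = joint_entropy(col_k, col_l, base)
    return raw / h if h > 0 else raw


def mib_normalized(col_k, col_l, background, base=math.e):
    rows = pair_rows(col_k, col_l)
    pk, pl, joint = _marginals(rows)
    mk, ml = _modified(pk, background), _modified(pl, background)
    raw = sum(
        p * _log(p / (mk[a] * ml[b]), base) for (a, b), p in joint.items()
    )
    h = joint_entropy(col_k, col_l, base)
    return raw / h if h > 0 else raw


def _group_tables(rows):
    n = len(rows)
    marg_k, marg_l, joint = {}, {}, {}
    for ga, members_a in TAYLOR.items():
        marg_k[ga] = sum(1 for a, _ in rows if a in members_a) / n
        marg_l[ga] = sum(1 for _, b in rows if b in members_a) / n
        for gb, members_b in TAYLOR.items():
            c = sum(1 for a, b in rows if a in members_a and b in members_b)
            if c:
                joint[(ga, gb)] = c / n
    return marg_k, marg_l, joint


def group_joint_entropy(col_k, col_l, base=math.e):
    _, _, joint = _group_tables(pair_rows(col_k, col_l))
    return -sum(p * _log(p, base) for p in joint.values())


def mip_normalized(col_k, col_l, base=math.e):
    rows = pair_rows(col_k, col_l)
    marg_k, marg_l, joint = _group_tables(rows)
    raw = sum(
        p * _log(p / (marg_k[a] * marg_l[b]), base) for (a, b), p in joint.items()
    )
    h = -sum(p * _log(p, base) for p in joint.values())
    return raw / h if h > 0 else raw


def mibp_normalized(col_k, col_l, background, base=math.e):
    rows = pair_rows(col_k, col_l)
    marg_k, marg_l, joint = _group_tables(rows)
    qp = {g: sum(background[a] for a in members) for g, members in TAYLOR.items()}
    mk = _modified({g: p for g, p in marg_k.items() if p > 0}, qp)
    ml = _modified({g: p for g, p in marg_l.items() if p > 0}, qp)
    raw = sum(
        p * _log(p / (mk[a] * ml[b]), base) for (a, b), p in joint.items()
    )
    h = -sum(p * _log(p, base) for p in joint.values())
    return raw / h if h > 0 else raw


def brute_identity(row_a, row_b):
    shared = [(a, b) for a, b in zip(row_a, row_b) if a != GAP and b != GAP]
    if not shared:
        return 0.0
    return sum(1 for a, b in shared if a == b) / len(shared)
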
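"""Relative qPCR quantification and the nested permutation ANOVA.

Expression is quantified with the comparative Ct method: per biological
replicate, technical replicates are averaged per gene, delta_ct is the mean
target Ct minus the mean reference Ct, and relative expression is
2**(-delta_ct).

The linear model analysed on relative expression is

    y_ijkl = mu + A_i + L_j(i) + S_k + AS_ik + e_ijkl

with A the fixed arrangement effect, L the random line effect nested within
arrangement, S the fixed sex effect, AS their interaction, and e the
residual.  Sums of squares are Type III with sum-to-zero contrasts (exact
least-squares decomposition for unbalanced data).  F denominators follow
the mixed-model expectations: the arrangement F is tested over the
line-within-arrangement mean square; line, sex and interaction over the
error mean square.

Because 2**(-delta_ct) is log-normal when delta_ct is normal, parametric
P values are validated by a four-stage restricted permutation test, one
exchange scheme per term:

1. line:         observations re-shuffled among lines within each arrangement;
2. arrangement:  whole lines (with all their observations) reassigned to
                 arrangements, preserving group sizes;
3. sex:          sex labels exchanged within each line (a global exchange is
                 available as an option);
4. interaction:  observations shuffled freely across the four
                 arrangement x sex cells (a Freedman-Lane residual scheme is
                 available as an option).

Each stage reports p = (1 + #{permuted F >= observed F}) / (B + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateDataError,
    DesignError,
    PairingError,
    ParameterError,
)
from .io_formats import Arrangement, CtRecord, Gene, Sex

TERMS = ("arrangement", "line_within_arrangement", "sex", "arrangement_by_sex", "error")


@dataclass(frozen=True)
class CtObservation:
    """One biological replicate's relative expression measurement."""

    line_id: str
    arrangement: Arrangement
    sex: Sex
    bio_rep: int
    delta_ct: float

    def __post_init__(self):
        from .io_formats import parse_arrangement, parse_sex

        object.__setattr__(self, "arrangement", parse_arrangement(self.arrangement))
        object.__setattr__(self, "sex", parse_sex(self.sex))

    @property
    def rel_expr(self) -> float:
        return float(2.0 ** (-self.delta_ct))


def aggregate_and_transform(records: Sequence[CtRecord]) -> List[CtObservation]:
    """Average technical replicates per gene and form delta_ct per replicate.

    Raises :class:`PairingError` naming any biological replicate lacking a
    target or reference measurement.
    """
    groups: Dict[tuple, Dict[Gene, list]] = {}
    meta = {}
    for r in records:
        key = (r.line_id, r.sex, r.bio_rep)
        groups.setdefault(key, {}).setdefault(r.gene, []).append(r.ct)
        meta[key] = r.arrangement
    out = []
    for key in sorted(groups, key=lambda k: (k[0], k[1].value, k[2])):
        per_gene = groups[key]
        if Gene.TARGET not in per_gene or Gene.REFERENCE not in per_gene:
            missing = "reference" if Gene.REFERENCE not in per_gene else "target"
            raise PairingError(
                f"replicate line={key[0]} sex={key[1].value} bio_rep={key[2]} "
                f"has no {missing} measurements"
            )
        dct = float(np.mean(per_gene[Gene.TARGET]) - np.mean(per_gene[Gene.REFERENCE]))
        out.append(CtObservation(key[0], meta[key], key[1], key[2], dct))
    return out


@dataclass(frozen=True)
class AnovaRow:
    term: str
    df: int
    ss: float
    ms: float
    f: Optional[float]
    p_parametric: Optional[float]
    p_permutation: Optional[float] = None


@dataclass(frozen=True)
class AnovaTable:
    rows: tuple

    def __getitem__(self, term: str) -> AnovaRow:
        for row in self.rows:
            if row.term == term:
                return row
        raise KeyError(term)

    def with_permutation_p(self, p_by_term: Dict[str, float]) -> "AnovaTable":
        return AnovaTable(
            tuple(
                replace(row, p_permutation=p_by_term.get(row.term, row.p_permutation))
                for row in self.rows
            )
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "Source": row.term,
                    "d.f.": row.df,
                    "MS": row.ms,
                    "F": row.f,
                    "P (parametric)": row.p_parametric,
                    "P (permutation)": row.p_permutation,
                }
                for row in self.rows
            ],
            columns=["Source", "d.f.", "MS", "F", "P (parametric)", "P (permutation)"],
        )


class _Encoded:
    """Integer-coded design extracted from observations."""

    def __init__(self, obs: Sequence[CtObservation], response: str = "rel_expr"):
        if response not in ("rel_expr", "delta_ct"):
            raise ParameterError(f"unknown response {response!r}")
        lines = sorted({o.line_id for o in obs})
        self.line_index = {l: i for i, l in enumerate(lines)}
        self.n_lines = len(lines)
        line_arr = {}
        for o in obs:
            prev = line_arr.setdefault(o.line_id, o.arrangement)
            if prev is not o.arrangement:
                raise DesignError(f"line {o.line_id!r} appears under two arrangements")
        arrangements = sorted({a.value for a in line_arr.values()})
        if len(arrangements) != 2:
            raise DesignError(f"need exactly 2 arrangements, got {arrangements}")
        self.arr_levels = arrangements
        self.line_arr = np.array(
            [arrangements.index(line_arr[l].value) for l in lines], dtype=int
        )
        for a in (0, 1):
            if (self.line_arr == a).sum() < 2:
                raise DesignError("each arrangement needs >= 2 lines")
        self.line = np.array([self.line_index[o.line_id] for o in obs], dtype=int)
        self.sex = np.array([0 if o.sex is Sex.F else 1 for o in obs], dtype=int)
        self.y = np.array(
            [o.rel_expr if response == "rel_expr" else o.delta_ct for o in obs],
            dtype=float,
        )
        self.n = len(obs)
        # estimability: the model has no line x sex term, so it only needs
        # every line and every arrangement x sex cell occupied
        for l in range(self.n_lines):
            if not np.any(self.line == l):
                raise DesignError(f"line {lines[l]!r} has no observations")
        arr_obs = self.line_arr[self.line]
        for a in (0, 1):
            for s in (0, 1):
                if not np.any((arr_obs == a) & (self.sex == s)):
                    raise DesignError(
                        f"arrangement {self.arr_levels[a]} has no observations "
                        f"for sex {'F' if s == 0 else 'M'}"
                    )
        self.df_line = self.n_lines - 2
        self.df_error = self.n - 1 - 1 - self.df_line - 1 - 1
        if self.df_line < 1 or self.df_error < 1:
            raise DesignError("a model term has zero degrees of freedom")


def _line_contrasts(line: np.ndarray, line_arr: np.ndarray, n_lines: int) -> np.ndarray:
    """Sum-to-zero contrast columns for line nested within arrangement."""
    cols = []
    for a in (0, 1):
        members = np.flatnonzero(line_arr == a)
        ref = members[-1]
        for l in members[:-1]:
            cols.append((line == l).astype(float) - (line == ref).astype(float))
    return np.column_stack(cols)


def _design_blocks(enc_line, line_arr, sex):
    arr_obs = line_arr[enc_line]
    A = 1.0 - 2.0 * arr_obs
    S = 1.0 - 2.0 * sex
    AS = A * S
    L = _line_contrasts(enc_line, line_arr, len(line_arr))
    ones = np.ones_like(A)
    return ones, A, L, S, AS


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _ss_decomposition(line, line_arr, sex, y):
    """Type III sums of squares via reduced-model RSS differences."""
    ones, A, L, S, AS = _design_blocks(line, line_arr, sex)
    X_full = np.column_stack([ones, A, L, S, AS])
    rss_full = _rss(X_full, y)
    ss = {
        "arrangement": _rss(np.column_stack([ones, L, S, AS]), y) - rss_full,
        "line_within_arrangement": _rss(np.column_stack([ones, A, S, AS]), y) - rss_full,
        "sex": _rss(np.column_stack([ones, A, L, AS]), y) - rss_full,
        "arrangement_by_sex": _rss(np.column_stack([ones, A, L, S]), y) - rss_full,
    }
    return ss, rss_full


def fit_nested_anova(obs: Sequence[CtObservation], response: str = "rel_expr") -> AnovaTable:
    """Fit the nested mixed ANOVA and return the five-row table.

    F denominators: arrangement over the line MS; line, sex and the
    interaction over the error MS.  Parametric P values come from the F
    distribution with the corresponding degrees of freedom.
    """
    enc = _Encoded(obs, response=response)
    ss, rss_full = _ss_decomposition(enc.line, enc.line_arr, enc.sex, enc.y)
    scale = float(enc.y @ enc.y) or 1.0
    if rss_full <= 1e-12 * scale and all(v <= 1e-12 * scale for v in ss.values()):
        raise DegenerateDataError("response has no variance; F undefined")
    dfs = {
        "arrangement": 1,
        "line_within_arrangement": enc.df_line,
        "sex": 1,
        "arrangement_by_sex": 1,
        "error": enc.df_error,
    }
    ms = {t: ss[t] / dfs[t] for t in ss}
    ms_error = rss_full / enc.df_error
    if ms_error <= 0 or rss_full <= 1e-12 * scale:
        raise DegenerateDataError("zero error mean square")
    ms["error"] = ms_error
    denominators = {
        "arrangement": ("line_within_arrangement", dfs["line_within_arrangement"]),
        "line_within_arrangement": ("error", enc.df_error),
        "sex": ("error", enc.df_error),
        "arrangement_by_sex": ("error", enc.df_error),
    }
    rows = []
    for term in TERMS[:-1]:
        den_term, den_df = denominators[term]
        f = ms[term] / ms[den_term]
        p = float(stats.f.sf(f, dfs[term], den_df))
        rows.append(AnovaRow(term, dfs[term], float(ss[term]), float(ms[term]), float(f), p))
    rows.append(AnovaRow("error", enc.df_error, float(rss_full), float(ms_error), None, None))
    return AnovaTable(tuple(rows))


# ---------------------------------------------------------------------------
# four-stage restricted permutation test
# ---------------------------------------------------------------------------


def _projector(X: np.ndarray) -> np.ndarray:
    """Residual-maker matrix I - X (X'X)^- X'."""
    n = X.shape[0]
    return np.eye(n) - X @ np.linalg.pinv(X)


def _perm_line(enc: _Encoded, rng, B: int, f_obs: float) -> float:
    """Stage 1: permute line membership within each arrangement."""
    ones, A, L, S, AS = _design_blocks(enc.line, enc.line_arr, enc.sex)
    X0 = np.column_stack([ones, A, S, AS])
    M0 = _projector(X0)
    y_t = M0 @ enc.y
    yty = float(y_t @ y_t)  # RSS of the no-line model
    arr_obs = enc.line_arr[enc.line]
    blocks = [np.flatnonzero(arr_obs == a) for a in (0, 1)]
    hits = 0
    for _ in range(B):
        perm = np.arange(enc.n)
        for idx in blocks:
            perm[idx] = idx[rng.permutation(len(idx))]
        Lt = M0 @ L[perm]
        G = Lt.T @ Lt
        b = Lt.T @ y_t
        coef = np.linalg.lstsq(G, b, rcond=None)[0]
        rss_full = yty - float(b @ coef)
        ss_line = yty - rss_full
        f = (ss_line / enc.df_line) / (rss_full / enc.df_error)
        if f >= f_obs:
            hits += 1
    return (hits + 1) / (B + 1)


def _perm_arrangement(enc: _Encoded, rng, B: int, f_obs: float) -> float:
    """Stage 2: reassign whole lines to arrangements, preserving sizes."""
    ones = np.ones(enc.n)
    S = 1.0 - 2.0 * enc.sex
    line_dummies = np.eye(enc.n_lines)[enc.line]  # n x n_lines
    # the full-model span is [line dummies, S, AS]; only AS varies with the
    # permuted assignment, so project it onto the fixed part once
    M_DS = _projector(np.column_stack([line_dummies, S]))
    y_t = M_DS @ enc.y
    yty = float(y_t @ y_t)
    M_1S = _projector(np.column_stack([ones, S]))
    y_1s = M_1S @ enc.y
    hits = 0
    for _ in range(B):
        la = enc.line_arr[rng.permutation(enc.n_lines)]
        arr_obs = la[enc.line]
        A = 1.0 - 2.0 * arr_obs
        AS = A * S
        u = M_DS @ AS
        uu = float(u @ u)
        rss_full = yty - (float(u @ y_t) ** 2 / uu if uu > 1e-12 else 0.0)
        # no-line model [1, A, S, AS]
        rss_noline = _rss(np.column_stack([ones, A, S, AS]), enc.y)
        # no-arrangement model [1, L, S, AS] via FWL over [1, S]
        L = _line_contrasts(enc.line, la, enc.n_lines)
        Z = M_1S @ np.column_stack([L, AS])
        G = Z.T @ Z
        b = Z.T @ y_1s
        coef = np.linalg.lstsq(G, b, rcond=None)[0]
        rss_noarr = float(y_1s @ y_1s) - float(b @ coef)
        ss_arr = rss_noarr - rss_full
        ss_line = rss_noline - rss_full
        f = ss_arr / max(ss_line / enc.df_line, 1e-300)
        if f >= f_obs:
            hits += 1
    return (hits + 1) / (B + 1)


def _perm_quadratic(
    enc: _Encoded,
    rng,
    B: int,
    f_obs: float,
    drop: str,
    blocks: Optional[list],
    df_num: int,
) -> float:
    """Stages 3/4 fast path: the permutation is equivalent to permuting the
    response (within blocks, or freely), so both RSS are quadratic forms in
    fixed residual-maker matrices."""
    ones, A, L, S, AS = _design_blocks(enc.line, enc.line_arr, enc.sex)
    X_full = np.column_stack([ones, A, L, S, AS])
    parts = {"sex": [ones, A, L, AS], "arrangement_by_sex": [ones, A, L, S]}
    M_full = _projector(X_full)
    M_red = _projector(np.column_stack(parts[drop]))
    idx = np.empty((B, enc.n), dtype=int)
    base = np.arange(enc.n)
    for b in range(B):
        perm = base.copy()
        if blocks is None:
            perm = rng.permutation(enc.n)
        else:
            for blk in blocks:
                perm[blk] = blk[rng.permutation(len(blk))]
        idx[b] = perm
    Y = enc.y[idx].T  # n x B
    rss_full = np.einsum("ij,jb,ib->b", M_full, Y, Y, optimize=True)
    rss_red = np.einsum("ij,jb,ib->b", M_red, Y, Y, optimize=True)
    f = ((rss_red - rss_full) / df_num) / (rss_full / enc.df_error)
    hits = int(np.sum(f >= f_obs))
    return (hits + 1) / (B + 1)


def _perm_sex_global(enc: _Encoded, rng, B: int, f_obs: float) -> float:
    """Optional global exchange of sex labels across all observations."""
    ones, A, L, S, AS = _design_blocks(enc.line, enc.line_arr, enc.sex)
    hits = 0
    for _ in range(B):
        perm = rng.permutation(enc.n)
        Sp = S[perm]
        ASp = A * Sp
        rss_full = _rss(np.column_stack([ones, A, L, Sp, ASp]), enc.y)
        rss_red = _rss(np.column_stack([ones, A, L, ASp]), enc.y)
        f = (rss_red - rss_full) / (rss_full / enc.df_error)
        if f >= f_obs:
            hits += 1
    return (hits + 1) / (B + 1)


def _perm_interaction_freedman_lane(enc: _Encoded, rng, B: int, f_obs: float) -> float:
    """Optional Freedman-Lane scheme: permute reduced-model residuals."""
    ones, A, L, S, AS = _design_blocks(enc.line, enc.line_arr, enc.sex)
    X_red = np.column_stack([ones, A, L, S])
    X_full = np.column_stack([ones, A, L, S, AS])
    M_red = _projector(X_red)
    M_full = _projector(X_full)
    fitted_red = enc.y - M_red @ enc.y
    resid_red = M_red @ enc.y
    idx = np.array([rng.permutation(enc.n) for _ in range(B)])
    Y = (fitted_red[:, None] + resid_red[idx].T)
    rss_full = np.einsum("ij,jb,ib->b", M_full, Y, Y, optimize=True)
    rss_red = np.einsum("ij,jb,ib->b", M_red, Y, Y, optimize=True)
    f = (rss_red - rss_full) / (rss_full / enc.df_error)
    hits = int(np.sum(f >= f_obs))
    return (hits + 1) / (B + 1)


def permutation_anova(
    obs: Sequence[CtObservation],
    n_permutations: int = 9999,
    seed: int = 0,
    response: str = "rel_expr",
    sex_scheme: str = "within_line",
    interaction_scheme: str = "cells",
) -> Dict[str, float]:
    """Per-term permutation P values from the four-stage restricted test.

    Each stage mixes its index into the seed, so stages are independently
    reproducible.  The smallest attainable p is 1/(n_permutations + 1).
    """
    if n_permutations < 1:
        raise ParameterError("n_permutations must be >= 1")
    if sex_scheme not in ("within_line", "global"):
        raise ParameterError(f"unknown sex_scheme {sex_scheme!r}")
    if interaction_scheme not in ("cells", "freedman_lane"):
        raise ParameterError(f"unknown interaction_scheme {interaction_scheme!r}")
    table = fit_nested_anova(obs, response=response)
    enc = _Encoded(obs, response=response)
    B = n_permutations
    out = {}

    rng1 = np.random.default_rng([seed, 1])
    out["line_within_arrangement"] = _perm_line(
        enc, rng1, B, table["line_within_arrangement"].f
    )

    rng2 = np.random.default_rng([seed, 2])
    out["arrangement"] = _perm_arrangement(enc, rng2, B, table["arrangement"].f)

    rng3 = np.random.default_rng([seed, 3])
    if sex_scheme == "within_line":
        blocks = [np.flatnonzero(enc.line == l) for l in range(enc.n_lines)]
        out["sex"] = _perm_quadratic(enc, rng3, B, table["sex"].f, "sex", blocks, 1)
    else:
        out["sex"] = _perm_sex_global(enc, rng3, B, table["sex"].f)

    rng4 = np.random.default_rng([seed, 4])
    if interaction_scheme == "cells":
        out["arrangement_by_sex"] = _perm_quadratic(
            enc, rng4, B, table["arrangement_by_sex"].f, "arrangement_by_sex", None, 1
        )
    else:
        out["arrangement_by_sex"] = _perm_interaction_freedman_lane(
            enc, rng4, B, table["arrangement_by_sex"].f
        )
    return out


@dataclass(frozen=True)
class ReferenceGeneCheck:
    """Homogeneity checks of the reference gene across the 4 sex x arrangement groups."""

    group_means: dict
    anova_f: float
    anova_p: float
    levene_w: float
    levene_p: float
    levene_mean_w: float
    levene_mean_p: float


def reference_gene_check(records: Sequence[CtRecord], min_per_group: int = 2) -> ReferenceGeneCheck:
    """One-way ANOVA and Levene's tests on reference-gene Ct values.

    Technical replicates are averaged per biological replicate first; the
    four groups are the sex x arrangement cells.  Levene's statistic is
    reported both median-centred (Brown-Forsythe) and mean-centred.
    """
    per_rep: Dict[tuple, list] = {}
    for r in records:
        if r.gene is not Gene.REFERENCE:
            continue
        per_rep.setdefault((r.arrangement, r.sex, r.line_id, r.bio_rep), []).append(r.ct)
    groups: Dict[tuple, list] = {}
    for (arr, sex, _line, _rep), cts in per_rep.items():
        groups.setdefault((arr, sex), []).append(float(np.mean(cts)))
    cells = [
        (Arrangement.OST, Sex.F),
        (Arrangement.OST, Sex.M),
        (Arrangement.O347, Sex.F),
        (Arrangement.O347, Sex.M),
    ]
    samples = []
    for cell in cells:
        values = groups.get(cell, [])
        if len(values) < min_per_group:
            raise DesignError(
                f"group {cell[0].value}/{cell[1].value} has fewer than "
                f"{min_per_group} observations"
            )
        samples.append(np.asarray(values))
    f, p = stats.f_oneway(*samples)
    if all(np.ptp(s) == 0 for s in samples):
        # zero spread in every group: Levene's W is 0 by convention
        w_med = w_mean = 0.0
        p_med = p_mean = 1.0
    else:
        w_med, p_med = stats.levene(*samples, center="median")
        w_mean, p_mean = stats.levene(*samples, center="mean")
    means = {
        f"{cell[0].value}_{cell[1].value}": float(np.mean(vals))
        for cell, vals in zip(cells, samples)
    }
    return ReferenceGeneCheck(
        means, float(f), float(p), float(w_med), float(p_med), float(w_mean), float(p_mean)
    )
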
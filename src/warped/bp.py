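"""Warp: carrier-posterior inference on pedigrees by belief propagation.

The model places a latent two-state carrier variable ``C`` on every
individual.  ``C = 0`` encodes the null model (offspring sex is a fair
coin, nothing is heritable); ``C = 1`` encodes the distortion model (a
carrier father's child is of the favored sex with probability
``penetrance``, and carrier status is transmitted down the relevant sex
chromosome up to a small de novo gain/loss rate).  The observed sexes are
the only evidence.  Marginal posteriors P(C=1 | all recorded sexes) are
computed by sum-product message passing on a factor graph whose factor
nodes are nuclear families, which is exact on non-inbred pedigrees and
iterates to convergence ("loopy" BP) when inbreeding creates cycles.

Two inheritance modes are supported:

``male_bias_Y``
    The distorter rides the Y chromosome.  Only males can carry; a
    carrier father's sons inherit (minus de novo loss) and his children
    are male with probability ``penetrance``.

``female_bias_X``
    The distorter rides the X.  Either sex can carry (one copy at most);
    a carrier father passes it to his daughters, a carrier mother to half
    her children, and distortion of the sex ratio acts only through
    carrier fathers, whose children are female with probability
    ``penetrance``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree

MODE_MALE_Y = "male_bias_Y"
MODE_FEMALE_X = "female_bias_X"
_MODE_ALIASES = {
    "male": MODE_MALE_Y, "y": MODE_MALE_Y, MODE_MALE_Y.lower(): MODE_MALE_Y,
    "female": MODE_FEMALE_X, "x": MODE_FEMALE_X, MODE_FEMALE_X.lower(): MODE_FEMALE_X,
}

#: parameter grid reported for the model-selection sweep
PENETRANCE_GRID = (
    0.50, 0.60, 0.62, 0.64, 0.66, 0.68, 0.70,
    0.75, 0.80, 0.85, 0.90, 0.95, 0.97, 0.99,
)
ALLELE_FREQ_GRID = (1e-3, 1e-4, 1e-5, 1e-6)
DE_NOVO_GRID = (1e-2, 1e-3, 1e-4, 1e-5, 1e-6)


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ModelParams:
    """Genetic model for one Warp run.

    penetrance
        P(child is of the favored sex | carrier father); 0.5 recovers the
        null model exactly.
    allele_freq
        Founder prior probability of carrying the distorter.
    de_novo_rate
        Per-transmission probability of gaining or losing carrier status.
    null_sex_prob
        P(male child) under the null; fixed at 0.5.
    mode
        ``male_bias_Y`` (favored sex male) or ``female_bias_X`` (favored
        sex female).
    """

    penetrance: float = 0.90
    allele_freq: float = 0.01
    de_novo_rate: float = 1e-6
    null_sex_prob: float = 0.5
    mode: str = MODE_MALE_Y

    def __post_init__(self) -> None:
        mode = _MODE_ALIASES.get(str(self.mode).lower())
        if mode is None:
            raise ParameterError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        for name in ("penetrance", "allele_freq", "de_novo_rate", "null_sex_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.penetrance < self.null_sex_prob:
            raise ParameterError(
                "penetrance below the null sex probability: the favored sex "
                "must be favored"
            )

    @property
    def favored_sex(self) -> str:
        return MALE if self.mode == MODE_MALE_Y else FEMALE


@dataclass
class CarrierPosterior:
    """Per-individual P(carrier | observed sexes) plus convergence info."""

    values: dict[str, float]
    n_sweeps: int
    converged: bool

    def max_id(self) -> str:
        """Id with the highest posterior (ties broken by smallest id)."""
        if not self.values:
            raise ValueError("empty posterior map")
        return min(self.values, key=lambda i: (-self.values[i], i))

    def max_value(self) -> float:
        if not self.values:
            raise ValueError("empty posterior map")
        return max(self.values.values())


# -- model terms ------------------------------------------------------------


def _sex_evidence(sex: str, favored: str, penetrance: float) -> tuple[float, float]:
    """(P(sex | C_father=0), P(sex | C_father=1)); unknown sex -> (1, 1)."""
    if sex == favored:
        return 0.5, penetrance
    if sex in (MALE, FEMALE):
        return 0.5, 1.0 - penetrance
    return 1.0, 1.0


def _y_carrier_prob(child_sex: str, c_father: int, dn: float) -> float:
    """P(C_child=1 | C_father, child sex), Y mode. Non-males cannot carry."""
    if child_sex != MALE:
        return 0.0
    return 1.0 - dn if c_father else dn


def _x_carrier_prob(
    child_sex: str, c_father: int, c_mother: int, dn: float
) -> float:
    """P(C_child=1 | parents), X mode, one-copy cap.

    Paternal, maternal and de novo channels act as independent routes of
    acquisition: a carrier father reaches daughters only, a carrier
    (heterozygous) mother reaches each child with probability one half.
    """
    p_pat = (1.0 - dn) if (c_father and child_sex == FEMALE) else 0.0
    p_mat = 0.5 * (1.0 - dn) if c_mother else 0.0
    return 1.0 - (1.0 - p_pat) * (1.0 - p_mat) * (1.0 - dn)


# -- factor graph -----------------------------------------------------------


@dataclass
class _Family:
    parents: tuple[int, ...]          # variable indices, father first if present
    children: list[int]
    # tables[j][combo] = (psi(combo, C_child=0), psi(combo, C_child=1));
    # the child's sex evidence term is folded in
    tables: list[list[tuple[float, float]]]
    depth: int


@dataclass
class BeliefNetwork:
    """Factor-graph form of the Warp model over one pedigree."""

    ids: list[str]
    priors: list[tuple[float, float]]          # unary potential per variable
    families: list[_Family]
    var_as_parent: list[list[tuple[int, int]]]  # var -> [(family, parent slot)]
    var_as_child: list[list[tuple[int, int]]]   # var -> [(family, child slot)]
    params: ModelParams = field(default=None)  # type: ignore[assignment]


def build_network(ped: Pedigree, params: ModelParams) -> BeliefNetwork:
    """Construct the belief network (CPTs evaluated at the observed sexes).

    Y mode families are keyed by the father alone (the mother's carrier
    state is irrelevant to a Y distorter); X mode families are keyed by the
    couple.  An absent parent contributes a fixed non-carrier channel.
    Individuals with no relevant recorded parent get the founder prior —
    except that in Y mode only males can carry, so female and sex-unknown
    roots are pinned to C=0.
    """
    ids = ped.ids
    index = {iid: k for k, iid in enumerate(ids)}
    depths = ped.generation_depths()
    p = params.penetrance
    dn = params.de_novo_rate
    af = params.allele_freq
    favored = params.favored_sex
    y_mode = params.mode == MODE_MALE_Y

    priors: list[tuple[float, float]] = []
    for iid in ids:
        ind = ped[iid]
        if y_mode:
            is_root = ind.father_id is None
            can_carry = ind.sex == MALE
        else:
            is_root = ind.father_id is None and ind.mother_id is None
            can_carry = True
        if not is_root:
            priors.append((1.0, 1.0))
        elif can_carry:
            priors.append((1.0 - af, af))
        else:
            priors.append((1.0, 0.0))

    # group children into family factors
    groups: dict[tuple, list[str]] = {}
    for ind in ped:
        if y_mode:
            if ind.father_id is None:
                continue
            key = (ind.father_id,)
        else:
            if ind.father_id is None and ind.mother_id is None:
                continue
            key = (ind.father_id, ind.mother_id)
        groups.setdefault(key, []).append(ind.id)

    families: list[_Family] = []
    for key in sorted(groups, key=lambda k: tuple(x or "" for x in k)):
        kids = sorted(groups[key])
        present = tuple(pid for pid in key if pid is not None)
        parent_idx = tuple(index[pid] for pid in present)
        n_par = len(present)
        combos = list(itertools.product((0, 1), repeat=n_par))
        tables = []
        for kid in kids:
            child = ped[kid]
            tab = []
            for combo in combos:
                if y_mode:
                    cf = combo[0]
                    cm = 0
                else:
                    state = dict(zip(present, combo))
                    cf = state.get(key[0], 0) if key[0] is not None else 0
                    cm = state.get(key[1], 0) if key[1] is not None else 0
                s0, s1 = _sex_evidence(child.sex, favored, p)
                sev = s1 if cf else s0
                if key[0] is None:
                    sev = s0  # no father on record: null sex probability
                if y_mode:
                    q = _y_carrier_prob(child.sex, cf, dn)
                else:
                    q = _x_carrier_prob(child.sex, cf, cm, dn)
                tab.append((sev * (1.0 - q), sev * q))
            tables.append(tab)
        families.append(
            _Family(
                parents=parent_idx,
                children=[index[k] for k in kids],
                tables=tables,
                depth=min(depths[pid] for pid in present) if present else 0,
            )
        )

    var_as_parent: list[list[tuple[int, int]]] = [[] for _ in ids]
    var_as_child: list[list[tuple[int, int]]] = [[] for _ in ids]
    for fi, fam in enumerate(families):
        for slot, v in enumerate(fam.parents):
            var_as_parent[v].append((fi, slot))
        for slot, v in enumerate(fam.children):
            var_as_child[v].append((fi, slot))
    return BeliefNetwork(
        ids=ids,
        priors=priors,
        families=families,
        var_as_parent=var_as_parent,
        var_as_child=var_as_child,
        params=params,
    )


def _normalize(m0: float, m1: float) -> tuple[float, float]:
    s = m0 + m1
    if s <= 0.0:
        return 0.5, 0.5
    return m0 / s, m1 / s


class _BPState:
    """Message store for one run of sum-product on a :class:`BeliefNetwork`."""

    def __init__(self, net: BeliefNetwork) -> None:
        self.net = net
        self.to_parent = [
            [(1.0, 1.0)] * len(f.parents) for f in net.families
        ]
        self.to_child = [
            [(1.0, 1.0)] * len(f.children) for f in net.families
        ]

    def _var_to_factor(self, v: int, fi: int, slot_kind: str, slot: int):
        net = self.net
        m0, m1 = net.priors[v]
        for gi, gslot in net.var_as_parent[v]:
            if slot_kind == "parent" and gi == fi and gslot == slot:
                continue
            g0, g1 = self.to_parent[gi][gslot]
            m0 *= g0
            m1 *= g1
        for gi, gslot in net.var_as_child[v]:
            if slot_kind == "child" and gi == fi and gslot == slot:
                continue
            g0, g1 = self.to_child[gi][gslot]
            m0 *= g0
            m1 *= g1
        return _normalize(m0, m1)

    def _child_sums(self, fi: int):
        """a_j[combo] = sum_c psi_j(combo, c) * mu_{child_j -> F}[c]."""
        fam = self.net.families[fi]
        out = []
        for slot, (v, tab) in enumerate(zip(fam.children, fam.tables)):
            mu0, mu1 = self._var_to_factor(v, fi, "child", slot)
            out.append([t0 * mu0 + t1 * mu1 for (t0, t1) in tab])
        return out

    def update_to_parents(self, fi: int, damping: float) -> None:
        fam = self.net.families[fi]
        if not fam.parents:
            return
        n_combo = len(fam.tables[0]) if fam.tables else 1
        a = self._child_sums(fi)
        all_a = [1.0] * n_combo
        for aj in a:
            for c in range(n_combo):
                all_a[c] *= aj[c]
        par_mu = [
            self._var_to_factor(v, fi, "parent", slot)
            for slot, v in enumerate(fam.parents)
        ]
        n_par = len(fam.parents)
        for slot in range(n_par):
            out = [0.0, 0.0]
            for combo in range(n_combo):
                # combo bit layout matches itertools.product((0,1), repeat=n)
                w = all_a[combo]
                state = None
                for other in range(n_par):
                    bit = (combo >> (n_par - 1 - other)) & 1
                    if other == slot:
                        state = bit
                    else:
                        w *= par_mu[other][bit]
                out[state] += w
            new = _normalize(out[0], out[1])
            if damping:
                old = self.to_parent[fi][slot]
                new = _normalize(
                    (1 - damping) * new[0] + damping * old[0],
                    (1 - damping) * new[1] + damping * old[1],
                )
            self.to_parent[fi][slot] = new

    def update_to_children(self, fi: int, damping: float) -> None:
        fam = self.net.families[fi]
        n_combo = len(fam.tables[0]) if fam.tables else 1
        a = self._child_sums(fi)
        n_kids = len(fam.children)
        # prefix/suffix products of the a_j over children, per combo
        prefix = [[1.0] * n_combo for _ in range(n_kids + 1)]
        for j in range(n_kids):
            for c in range(n_combo):
                prefix[j + 1][c] = prefix[j][c] * a[j][c]
        suffix = [[1.0] * n_combo for _ in range(n_kids + 1)]
        for j in range(n_kids - 1, -1, -1):
            for c in range(n_combo):
                suffix[j][c] = suffix[j + 1][c] * a[j][c]
        n_par = len(fam.parents)
        parw = [1.0] * n_combo
        if n_par:
            par_mu = [
                self._var_to_factor(v, fi, "parent", slot)
                for slot, v in enumerate(fam.parents)
            ]
            for combo in range(n_combo):
                w = 1.0
                for pslot in range(n_par):
                    bit = (combo >> (n_par - 1 - pslot)) & 1
                    w *= par_mu[pslot][bit]
                parw[combo] = w
        for j in range(n_kids):
            tab = fam.tables[j]
            m0 = m1 = 0.0
            for combo in range(n_combo):
                w = parw[combo] * prefix[j][combo] * suffix[j + 1][combo]
                t0, t1 = tab[combo]
                m0 += w * t0
                m1 += w * t1
            new = _normalize(m0, m1)
            if damping:
                old = self.to_child[fi][j]
                new = _normalize(
                    (1 - damping) * new[0] + damping * old[0],
                    (1 - damping) * new[1] + damping * old[1],
                )
            self.to_child[fi][j] = new

    def posteriors(self) -> list[float]:
        net = self.net
        out = []
        for v in range(len(net.ids)):
            m0, m1 = net.priors[v]
            for gi, gslot in net.var_as_parent[v]:
                g0, g1 = self.to_parent[gi][gslot]
                m0 *= g0
                m1 *= g1
            for gi, gslot in net.var_as_child[v]:
                g0, g1 = self.to_child[gi][gslot]
                m0 *= g0
                m1 *= g1
            s = m0 + m1
            out.append(m1 / s if s > 0.0 else 0.0)
        return out


def run_belief_propagation(
    net: BeliefNetwork,
    tol: float = 1e-9,
    max_sweeps: int = 100,
    damping: float = 0.0,
) -> CarrierPosterior:
    """Sum-product message passing with generation-ordered sweeps.

    One sweep passes messages from the deepest families up to the founders
    and then back down.  Converged when the largest absolute change in any
    posterior between consecutive sweeps falls below ``tol``; on tree
    pedigrees the second sweep confirms the first.  Non-convergence inside
    ``max_sweeps`` (possible on inbred, loopy pedigrees) is flagged, not
    raised; ``damping`` in [0, 1) mixes in the previous messages to settle
    oscillations on such loops.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    if max_sweeps < 1:
        raise ParameterError("max_sweeps must be >= 1")
    if not (0.0 <= damping < 1.0):
        raise ParameterError("damping must be in [0, 1)")
    state = _BPState(net)
    order_up = sorted(range(len(net.families)),
                      key=lambda fi: -net.families[fi].depth)
    order_down = order_up[::-1]
    prev = state.posteriors()
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        for fi in order_up:
            state.update_to_parents(fi, damping)
        for fi in order_down:
            state.update_to_children(fi, damping)
        cur = state.posteriors()
        delta = max(
            (abs(a - b) for a, b in zip(cur, prev)), default=0.0
        )
        prev = cur
        if delta < tol:
            converged = True
            break
    return CarrierPosterior(
        values=dict(zip(net.ids, prev)), n_sweeps=sweeps, converged=converged
    )


def run_warp(
    ped: Pedigree,
    params: ModelParams,
    tol: float = 1e-9,
    max_sweeps: int = 100,
    damping: float = 0.0,
) -> CarrierPosterior:
    """Build the network for ``ped`` and run belief propagation."""
    return run_belief_propagation(
        build_network(ped, params), tol=tol, max_sweeps=max_sweeps,
        damping=damping,
    )


# -- independent oracle -----------------------------------------------------


def exact_posterior_enumeration(
    ped: Pedigree, params: ModelParams, max_size: int = 20
) -> CarrierPosterior:
    """Exact carrier marginals by summing over all 2^n carrier assignments.

    Written directly from the generative model (not from the factor graph)
    so it can serve as an independent check on belief propagation.  Cost is
    exponential; refuses pedigrees larger than ``max_size``.
    """
    n = len(ped)
    if n > max_size:
        raise ValueError(
            f"pedigree has {n} individuals; exact enumeration is exponential "
            f"and limited to {max_size} — use run_warp instead"
        )
    ids = ped.ids
    pos = {iid: k for k, iid in enumerate(ids)}
    p = params.penetrance
    dn = params.de_novo_rate
    af = params.allele_freq
    favored = params.favored_sex
    y_mode = params.mode == MODE_MALE_Y

    total = 0.0
    marg = [0.0] * n
    for bits in itertools.product((0, 1), repeat=n):
        w = 1.0
        for k, iid in enumerate(ids):
            ind = ped[iid]
            ci = bits[k]
            cf = bits[pos[ind.father_id]] if ind.father_id is not None else None
            # sex evidence through the father
            if cf is not None and ind.sex in (MALE, FEMALE):
                if ind.sex == favored:
                    w *= p if cf else 0.5
                else:
                    w *= (1.0 - p) if cf else 0.5
            # carrier state
            if y_mode:
                if ind.sex != MALE:
                    q = 0.0
                elif ind.father_id is None:
                    q = af
                else:
                    q = 1.0 - dn if cf else dn
            else:
                if ind.father_id is None and ind.mother_id is None:
                    q = af
                else:
                    cm = (
                        bits[pos[ind.mother_id]]
                        if ind.mother_id is not None
                        else 0
                    )
                    q = _x_carrier_prob(ind.sex, cf or 0, cm, dn)
            w *= q if ci else 1.0 - q
            if w == 0.0:
                break
        if w == 0.0:
            continue
        total += w
        for k in range(n):
            if bits[k]:
                marg[k] += w
    values = {
        iid: (marg[k] / total if total > 0 else 0.0)
        for k, iid in enumerate(ids)
    }
    return CarrierPosterior(values=values, n_sweeps=1, converged=True)


def single_sibship_posterior(
    n_favored: int, n_other: int, params: ModelParams
) -> float:
    """Closed-form carrier posterior for a founder father of one sibship.

    Bayes' rule with prior ``allele_freq``: the distortion model explains
    the sibship with ``penetrance^m (1-penetrance)^f`` against the null's
    ``0.5^(m+f)``.
    """
    if n_favored < 0 or n_other < 0:
        raise ValueError("offspring counts must be >= 0")
    pi = params.allele_freq
    p = params.penetrance
    num = pi * p**n_favored * (1.0 - p) ** n_other
    den = num + (1.0 - pi) * 0.5 ** (n_favored + n_other)
    return num / den


def sweep_parameters(
    ped: Pedigree,
    penetrances: Sequence[float] = PENETRANCE_GRID,
    allele_freqs: Sequence[float] = ALLELE_FREQ_GRID,
    de_novo_rates: Sequence[float] = DE_NOVO_GRID,
    mode: str = MODE_MALE_Y,
    tol: float = 1e-9,
    max_sweeps: int = 100,
) -> pd.DataFrame:
    """Run Warp over a parameter grid; one row per combination.

    Columns: penetrance, allele_freq, de_novo_rate, max_posterior,
    argmax_id, n_sweeps, converged.  Row order follows the input grids
    (penetrance outermost), so output is deterministic.
    """
    if not (penetrances and allele_freqs and de_novo_rates):
        raise ValueError("parameter grids must be non-empty")
    rows = []
    for pen, af, dn in itertools.product(penetrances, allele_freqs, de_novo_rates):
        params = ModelParams(
            penetrance=pen, allele_freq=af, de_novo_rate=dn, mode=mode
        )
        post = run_warp(ped, params, tol=tol, max_sweeps=max_sweeps)
        rows.append(
            {
                "penetrance": pen,
                "allele_freq": af,
                "de_novo_rate": dn,
                "max_posterior": post.max_value(),
                "argmax_id": post.max_id(),
                "n_sweeps": post.n_sweeps,
                "converged": post.converged,
            }
        )
    return pd.DataFrame(rows)
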
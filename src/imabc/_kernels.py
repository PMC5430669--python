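"""Numba hot path for the structured-coalescent simulator.

All kernels share one convention: time runs backwards from the present in
coalescent units where a pair of lineages within a deme coalesces at rate 1
and mutations fall at rate theta_locus/2 per unit of branch length.  The
numba global RNG is seeded explicitly by the ``*_seeded`` wrappers; the
unseeded kernels consume the current stream, which is what lets a fused
multi-locus simulation replay exactly the per-locus object path.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# deme codes
WEST = 0
EAST = 1


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def sim_genealogy(n_west, n_east, T, M, mig_until):
    """Two-deme structured coalescent genealogy.

    Leaves 0..n_west-1 are west, the next n_east east.  Internal nodes are
    appended in coalescence order, so every parent id exceeds its children's
    ids and node times are non-decreasing in id.  Migration (rate M/2 per
    lineage, symmetric) operates only while t < mig_until; at t = T the two
    demes merge into the ancestral deme.

    Returns (parent, node_time); parent[root] = -1.
    """
    n = n_west + n_east
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes, dtype=np.float64)

    lineage_node = np.empty(n, dtype=np.int64)
    lineage_deme = np.empty(n, dtype=np.int64)
    for i in range(n):
        lineage_node[i] = i
        lineage_deme[i] = WEST if i < n_west else EAST
    k = n
    next_node = n
    t = 0.0
    merged = False

    while k > 1:
        kw = 0
        for i in range(k):
            if lineage_deme[i] == WEST:
                kw += 1
        ke = k - kw
        rate_cw = kw * (kw - 1) / 2.0
        rate_ce = ke * (ke - 1) / 2.0
        if merged:
            rate_mig = 0.0
        else:
            rate_mig = k * M / 2.0 if t < mig_until else 0.0
        total = rate_cw + rate_ce + rate_mig

        if not merged:
            # next deterministic epoch boundary
            boundary = mig_until if (t < mig_until and mig_until < T) else T
        else:
            boundary = np.inf

        if total <= 0.0:
            t = boundary
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= boundary:
                t = boundary
            else:
                t += dt
                u = np.random.random() * total
                if u < rate_cw or u < rate_cw + rate_ce:
                    deme = WEST if u < rate_cw else EAST
                    kd = kw if deme == WEST else ke
                    # pick an ordered pair uniformly among deme members
                    a = int(np.random.random() * kd)
                    b = int(np.random.random() * (kd - 1))
                    if b >= a:
                        b += 1
                    # map deme-local indices to lineage indices
                    ia = -1
                    ib = -1
                    seen = 0
                    for i in range(k):
                        if lineage_deme[i] == deme:
                            if seen == a:
                                ia = i
                            if seen == b:
                                ib = i
                            seen += 1
                    parent[lineage_node[ia]] = next_node
                    parent[lineage_node[ib]] = next_node
                    node_time[next_node] = t
                    lineage_node[ia] = next_node
                    # remove ib by swapping in the tail
                    lineage_node[ib] = lineage_node[k - 1]
                    lineage_deme[ib] = lineage_deme[k - 1]
                    next_node += 1
                    k -= 1
                else:
                    j = int(np.random.random() * k)
                    lineage_deme[j] = WEST if lineage_deme[j] == EAST else EAST
                continue

        # hit a boundary without an event
        if not merged and t >= T:
            merged = True
            for i in range(k):
                lineage_deme[i] = WEST
    return parent, node_time


@njit(cache=True)
def drop_mutations(parent, node_time, theta_half):
    """Poisson infinite-sites mutations on a genealogy.

    Returns (branch_nodes, positions): for each mutation the node below the
    mutated branch and a uniform position in [0, 1).  The root carries no
    branch.  Mutation order follows the Poisson draw; positions are i.i.d.
    """
    n_nodes = parent.shape[0]
    blen = np.zeros(n_nodes, dtype=np.float64)
    total = 0.0
    for v in range(n_nodes):
        p = parent[v]
        if p >= 0:
            blen[v] = node_time[p] - node_time[v]
            total += blen[v]
    n_mut = np.random.poisson(theta_half * total)
    branch_nodes = np.empty(n_mut, dtype=np.int64)
    positions = np.empty(n_mut, dtype=np.float64)
    if n_mut == 0:
        return branch_nodes, positions
    cum = np.cumsum(blen)
    for m in range(n_mut):
        r = np.random.random() * total
        v = np.searchsorted(cum, r, side="right")
        if v >= n_nodes:
            v = n_nodes - 1
        branch_nodes[m] = v
        positions[m] = np.random.random()
    return branch_nodes, positions


@njit(cache=True)
def descendant_counts(parent, n_west, n_east):
    """Per-node counts of west and east leaves below (inclusive of leaves)."""
    n_nodes = parent.shape[0]
    wc = np.zeros(n_nodes, dtype=np.int64)
    ec = np.zeros(n_nodes, dtype=np.int64)
    for i in range(n_west):
        wc[i] = 1
    for i in range(n_west, n_west + n_east):
        ec[i] = 1
    for v in range(n_nodes - 1):
        p = parent[v]
        if p >= 0:
            wc[p] += wc[v]
            ec[p] += ec[v]
    return wc, ec


@njit(cache=True)
def wh_classify_counts(branch_nodes, wc, ec, n_west, n_east):
    """Wakeley–Hey counts (private W, private E, shared, fixed) for mutations."""
    pw = 0
    pe = 0
    sh = 0
    fx = 0
    for m in range(branch_nodes.shape[0]):
        v = branch_nodes[m]
        w = wc[v]
        e = ec[v]
        poly_w = 0 < w < n_west
        poly_e = 0 < e < n_east
        if poly_w and poly_e:
            sh += 1
        elif poly_w:
            pw += 1
        elif poly_e:
            pe += 1
        else:
            fx += 1
    return pw, pe, sh, fx


@njit(cache=True)
def wh_dataset(n_west_arr, n_east_arr, theta_loc_arr, T, M, mig_until_frac):
    """Four summed Wakeley–Hey statistics for one multi-locus simulation.

    Consumes the current RNG stream; loci are simulated in order with the
    same kernel sequence as the object-level per-locus path.
    """
    out = np.zeros(4, dtype=np.int64)
    mig_until = mig_until_frac * T
    for l in range(n_west_arr.shape[0]):
        nw = n_west_arr[l]
        ne = n_east_arr[l]
        parent, node_time = sim_genealogy(nw, ne, T, M, mig_until)
        branch_nodes, _ = drop_mutations(parent, node_time, theta_loc_arr[l] / 2.0)
        wc, ec = descendant_counts(parent, nw, ne)
        pw, pe, sh, fx = wh_classify_counts(branch_nodes, wc, ec, nw, ne)
        out[0] += pw
        out[1] += pe
        out[2] += sh
        out[3] += fx
    return out


@njit(cache=True)
def rejection_count(
    n_west_arr,
    n_east_arr,
    theta_loc_arr,
    T,
    M,
    mig_until_frac,
    obs,
    eps_frac,
    per_component,
    seeds,
):
    """Number of accepted simulations at one grid point.

    per_component: each of the four across-locus sums must lie within
    ±eps_frac of its observed value (an observed zero demands a simulated
    zero).  Otherwise the single grand total is tested.
    """
    n_accepted = 0
    obs_total = obs[0] + obs[1] + obs[2] + obs[3]
    for s in range(seeds.shape[0]):
        np.random.seed(seeds[s])
        sim = wh_dataset(n_west_arr, n_east_arr, theta_loc_arr, T, M, mig_until_frac)
        if per_component:
            ok = True
            for j in range(4):
                if abs(sim[j] - obs[j]) > eps_frac * obs[j]:
                    ok = False
                    break
            if ok:
                n_accepted += 1
        else:
            if abs(sim[0] + sim[1] + sim[2] + sim[3] - obs_total) <= eps_frac * obs_total:
                n_accepted += 1
    return n_accepted
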
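"""Numba core for Vietoris-Rips persistent homology (dimensions 0-2).

The engine follows the persistent-cohomology scheme with clearing:

* H0 by Kruskal union-find over edges sorted by length — the merge edges
  are exactly the death simplices of the 0-dimensional classes, and the
  0-bars are (0, merge length).
* For dimension d in {1, 2}, the coboundary matrix is reduced: columns are
  d-simplices processed in decreasing filtration order, entries are their
  (d+1)-cofacets, and the pivot of a column is its cofacet that is minimal
  in the global simplex order.  A claimed pivot tau for column sigma yields
  the persistence pair (diam(sigma), diam(tau)) in dimension d.  Clearing
  skips columns that are known death simplices of dimension d-1.

Simplices are identified by their combinatorial (colex) index among the
sorted vertex tuples; the global order is (diameter, colex index)
ascending, which refines the filtration and puts faces before cofaces.

Performance notes (all exact, none approximate):

* Most columns claim their pivot without a single column addition, so the
  cofacet list is only sorted when a collision actually occurs, and a
  column claimed untouched is stored as just its vertex tuple — its raw
  coboundary is re-enumerated on demand.  Only columns that underwent
  additions are stored explicitly.
* The filtration is truncated at the *enclosing radius* (the min over
  points of the max distance to any other point).  At that scale the
  complex is a cone, hence contractible, so every class born below it has
  died and any class born at or above it has zero persistence; the
  positive-persistence diagram is unchanged while far fewer simplices
  enter the reduction.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from numba.core import types
from numba.typed import Dict, List

INT = types.int64


@njit(cache=True)
def _binom_table(n: int) -> np.ndarray:
    # B[v, j] = C(v, j) for j <= 4
    B = np.zeros((n + 1, 5), dtype=np.int64)
    for v in range(n + 1):
        B[v, 0] = 1
        for j in range(1, 5):
            if j > v:
                B[v, j] = 0
            else:
                B[v, j] = B[v - 1, j - 1] + B[v - 1, j]
    return B


@njit(cache=True)
def _sort_desc_inplace(diams, cidxs):
    """Sort parallel arrays descending by (diam, cidx); returns new arrays."""
    o1 = np.argsort(cidxs, kind="mergesort")
    d1 = diams[o1]
    c1 = cidxs[o1]
    o2 = np.argsort(d1, kind="mergesort")
    return d1[o2][::-1].copy(), c1[o2][::-1].copy()


@njit(cache=True)
def _xor_merge(da, ca, db, cb):
    """GF(2) sum of two columns sorted descending by (diam, cidx)."""
    na, nb = len(ca), len(cb)
    out_d = np.empty(na + nb, dtype=np.float64)
    out_c = np.empty(na + nb, dtype=np.int64)
    i = j = k = 0
    while i < na and j < nb:
        if ca[i] == cb[j]:
            i += 1
            j += 1
        else:
            if da[i] > db[j] or (da[i] == db[j] and ca[i] > cb[j]):
                out_d[k] = da[i]
                out_c[k] = ca[i]
                i += 1
            else:
                out_d[k] = db[j]
                out_c[k] = cb[j]
                j += 1
            k += 1
    while i < na:
        out_d[k] = da[i]
        out_c[k] = ca[i]
        i += 1
        k += 1
    while j < nb:
        out_d[k] = db[j]
        out_c[k] = cb[j]
        j += 1
        k += 1
    return out_d[:k].copy(), out_c[:k].copy()


@njit(cache=True)
def _find(parent, x):
    root = x
    while parent[root] != root:
        root = parent[root]
    while parent[x] != root:
        nxt = parent[x]
        parent[x] = root
        x = nxt
    return root


@njit(cache=True)
def _tri_cidx(B, a, b, c):
    """Colex index of the triangle on vertices {a, b} (a < b) and c."""
    if c > b:
        return B[c, 3] + B[b, 2] + a
    elif c > a:
        return B[b, 3] + B[c, 2] + a
    else:
        return B[b, 3] + B[a, 2] + c


@njit(cache=True)
def _tet_cidx(B, a, b, c, v):
    """Colex index of the tetrahedron on {a, b, c} (a < b < c) and v."""
    if v > c:
        return B[v, 4] + B[c, 3] + B[b, 2] + a
    elif v > b:
        return B[c, 4] + B[v, 3] + B[b, 2] + a
    elif v > a:
        return B[c, 4] + B[b, 3] + B[v, 2] + a
    else:
        return B[c, 4] + B[b, 3] + B[a, 2] + v


@njit(cache=True)
def _cofacets(dm, B, d, v0, v1, v2, sd, thresh, out_d, out_c):
    """Unsorted cofacet list of a d-simplex (d = 1 or 2); returns count."""
    n = dm.shape[0]
    m = 0
    if d == 1:
        for c in range(n):
            if c == v0 or c == v1:
                continue
            dt = sd
            if dm[v0, c] > dt:
                dt = dm[v0, c]
            if dm[v1, c] > dt:
                dt = dm[v1, c]
            if dt > thresh:
                continue
            out_d[m] = dt
            out_c[m] = _tri_cidx(B, v0, v1, c)
            m += 1
    else:
        for v in range(n):
            if v == v0 or v == v1 or v == v2:
                continue
            dq = sd
            if dm[v0, v] > dq:
                dq = dm[v0, v]
            if dm[v1, v] > dq:
                dq = dm[v1, v]
            if dm[v2, v] > dq:
                dq = dm[v2, v]
            if dq > thresh:
                continue
            out_d[m] = dq
            out_c[m] = _tet_cidx(B, v0, v1, v2, v)
            m += 1
    return m


@njit(cache=True)
def _reduce_dim(
    dm,
    B,
    thresh,
    d,  # dimension of the column simplices (1 or 2)
    sigma_v,  # ns x 3 vertex tuples, ascending filtration order
    sigma_diam,  # ns diameters, ascending
    keep_essential,  # False when the filtration was truncated internally
    births,
    deaths,
    dims,
    nbars,
    pivot_out,  # claimed pivot cidxs (for clearing the next dimension)
):
    n = dm.shape[0]
    ns = sigma_v.shape[0]
    scratch_d = np.empty(n, dtype=np.float64)
    scratch_c = np.empty(n, dtype=np.int64)

    pivots = Dict.empty(INT, INT)  # pivot cidx -> slot
    # slot storage: untouched columns keep only their simplex (kind 0);
    # columns that underwent additions store the reduced column (kind 1)
    kind = np.zeros(ns, dtype=np.uint8)
    slot_v = np.empty((ns, 3), dtype=np.int64)
    slot_diam = np.empty(ns, dtype=np.float64)
    slot_expl = np.full(ns, -1, dtype=np.int64)
    expl_d = List()
    expl_c = List()
    expl_d.append(np.empty(0, dtype=np.float64))  # typing seed
    expl_c.append(np.empty(0, dtype=np.int64))
    nslots = 0
    npiv = 0

    for t in range(ns - 1, -1, -1):  # descending filtration order
        v0 = sigma_v[t, 0]
        v1 = sigma_v[t, 1]
        v2 = sigma_v[t, 2]
        sd = sigma_diam[t]
        m = _cofacets(dm, B, d, v0, v1, v2, sd, thresh, scratch_d, scratch_c)
        if m == 0:
            if keep_essential:
                births[nbars] = sd
                deaths[nbars] = np.inf
                dims[nbars] = d
                nbars += 1
            continue
        # locate the pivot (minimal (diam, cidx)) without sorting
        pi = 0
        for q in range(1, m):
            if scratch_d[q] < scratch_d[pi] or (
                scratch_d[q] == scratch_d[pi] and scratch_c[q] < scratch_c[pi]
            ):
                pi = q
        piv = scratch_c[pi]
        if piv not in pivots:
            # untouched claim: remember only the simplex itself
            pivots[piv] = nslots
            slot_v[nslots, 0] = v0
            slot_v[nslots, 1] = v1
            slot_v[nslots, 2] = v2
            slot_diam[nslots] = sd
            nslots += 1
            pivot_out[npiv] = piv
            npiv += 1
            if scratch_d[pi] > sd:
                births[nbars] = sd
                deaths[nbars] = scratch_d[pi]
                dims[nbars] = d
                nbars += 1
            continue
        # collision: fall back to sorted reduction
        cur_d, cur_c = _sort_desc_inplace(
            scratch_d[:m].copy(), scratch_c[:m].copy()
        )
        while True:
            if len(cur_c) == 0:
                if keep_essential:
                    births[nbars] = sd
                    deaths[nbars] = np.inf
                    dims[nbars] = d
                    nbars += 1
                break
            piv = cur_c[len(cur_c) - 1]
            if piv in pivots:
                si = pivots[piv]
                if kind[si] == 0:
                    mm = _cofacets(
                        dm,
                        B,
                        d,
                        slot_v[si, 0],
                        slot_v[si, 1],
                        slot_v[si, 2],
                        slot_diam[si],
                        thresh,
                        scratch_d,
                        scratch_c,
                    )
                    od, oc = _sort_desc_inplace(
                        scratch_d[:mm].copy(), scratch_c[:mm].copy()
                    )
                    # cache the sorted form for future collisions
                    kind[si] = 1
                    slot_expl[si] = len(expl_d)
                    expl_d.append(od)
                    expl_c.append(oc)
                else:
                    od = expl_d[slot_expl[si]]
                    oc = expl_c[slot_expl[si]]
                cur_d, cur_c = _xor_merge(cur_d, cur_c, od, oc)
            else:
                pivots[piv] = nslots
                kind[nslots] = 1
                slot_expl[nslots] = len(expl_d)
                expl_d.append(cur_d)
                expl_c.append(cur_c)
                nslots += 1
                pivot_out[npiv] = piv
                npiv += 1
                pd = cur_d[len(cur_d) - 1]
                if pd > sd:
                    births[nbars] = sd
                    deaths[nbars] = pd
                    dims[nbars] = d
                    nbars += 1
                break
    return nbars, npiv


@njit(cache=True)
def _rips_pairs(dm: np.ndarray, maxdim: int, eps_max: float):
    """All positive-persistence and essential bars of the Rips filtration.

    ``eps_max`` is the requested filtration cutoff.  Internally the
    filtration is further truncated at the enclosing radius when that is
    smaller, which leaves the positive-persistence diagram and the
    essential classes unchanged (see module docstring).
    """
    n = dm.shape[0]
    B = _binom_table(n)

    # enclosing radius: min over vertices of the max distance to others
    enc = np.inf
    for i in range(n):
        mx = 0.0
        for j in range(n):
            if dm[i, j] > mx:
                mx = dm[i, j]
        if mx < enc:
            enc = mx
    truncated = enc < eps_max
    thresh = enc if truncated else eps_max
    # above the enclosing radius the complex is a cone: no class survives,
    # so dim >= 1 columns reducing to zero under truncation are artifacts
    keep_essential = not truncated

    max_bars = n + n * (n - 1) // 2 + 2
    if maxdim >= 2:
        max_bars += n * (n - 1) * (n - 2) // 6
    births = np.empty(max_bars, dtype=np.float64)
    deaths = np.empty(max_bars, dtype=np.float64)
    dims = np.empty(max_bars, dtype=np.int64)
    nbars = 0

    # ---- edges, ascending (diam, cidx) ---------------------------------
    ne = n * (n - 1) // 2
    e_i = np.empty(ne, dtype=np.int64)
    e_j = np.empty(ne, dtype=np.int64)
    e_diam = np.empty(ne, dtype=np.float64)
    p = 0
    for j in range(n):
        for i in range(j):
            e_i[p] = i
            e_j[p] = j
            e_diam[p] = dm[i, j]
            p += 1
    # enumeration is ascending in colex index; a stable sort by diameter
    # therefore yields the ascending (diam, cidx) order
    e_order = np.argsort(e_diam, kind="mergesort")

    # ---- H0 via union-find ---------------------------------------------
    parent = np.arange(n)
    is_merge = np.zeros(ne, dtype=np.bool_)
    n_comp = n
    for t in range(ne):
        e = e_order[t]
        if e_diam[e] > thresh:
            break
        ri = _find(parent, e_i[e])
        rj = _find(parent, e_j[e])
        if ri != rj:
            parent[ri] = rj
            is_merge[e] = True
            n_comp -= 1
            if e_diam[e] > 0.0:
                births[nbars] = 0.0
                deaths[nbars] = e_diam[e]
                dims[nbars] = 0
                nbars += 1
    for _ in range(n_comp):  # essential components (1 when connected)
        births[nbars] = 0.0
        deaths[nbars] = np.inf
        dims[nbars] = 0
        nbars += 1

    if maxdim < 1:
        return births[:nbars], deaths[:nbars], dims[:nbars]

    # ---- dimension 1: columns are the cycle edges ----------------------
    ncand = 0
    for t in range(ne):
        e = e_order[t]
        if not is_merge[e] and e_diam[e] <= thresh:
            ncand += 1
    sig_v = np.full((ncand, 3), -1, dtype=np.int64)
    sig_d = np.empty(ncand, dtype=np.float64)
    q = 0
    for t in range(ne):  # ascending order
        e = e_order[t]
        if is_merge[e] or e_diam[e] > thresh:
            continue
        sig_v[q, 0] = e_i[e]
        sig_v[q, 1] = e_j[e]
        sig_d[q] = e_diam[e]
        q += 1
    tri_pivots = np.empty(ncand + 1, dtype=np.int64)
    nbars, npiv1 = _reduce_dim(
        dm, B, thresh, 1, sig_v, sig_d, keep_essential,
        births, deaths, dims, nbars, tri_pivots,
    )

    if maxdim < 2:
        return births[:nbars], deaths[:nbars], dims[:nbars]

    # ---- dimension 2: columns are the non-cleared triangles ------------
    cleared = Dict.empty(INT, INT)
    for t in range(npiv1):
        cleared[tri_pivots[t]] = 1

    nt = B[n, 3]
    t_a = np.empty(nt, dtype=np.int64)
    t_b = np.empty(nt, dtype=np.int64)
    t_c = np.empty(nt, dtype=np.int64)
    t_diam = np.empty(nt, dtype=np.float64)
    p = 0
    for c in range(n):  # ascending colex: c > b > a
        for b in range(c):
            dbc = dm[b, c]
            for a in range(b):
                dt = dbc
                if dm[a, b] > dt:
                    dt = dm[a, b]
                if dm[a, c] > dt:
                    dt = dm[a, c]
                t_a[p] = a
                t_b[p] = b
                t_c[p] = c
                t_diam[p] = dt
                p += 1
    t_order = np.argsort(t_diam, kind="mergesort")

    ncand2 = 0
    for t in range(nt):
        tr = t_order[t]
        if t_diam[tr] > thresh:
            continue
        cidx = B[t_c[tr], 3] + B[t_b[tr], 2] + t_a[tr]
        if cidx in cleared:
            continue
        ncand2 += 1
    sig_v2 = np.empty((ncand2, 3), dtype=np.int64)
    sig_d2 = np.empty(ncand2, dtype=np.float64)
    q = 0
    for t in range(nt):
        tr = t_order[t]
        if t_diam[tr] > thresh:
            continue
        cidx = B[t_c[tr], 3] + B[t_b[tr], 2] + t_a[tr]
        if cidx in cleared:
            continue
        sig_v2[q, 0] = t_a[tr]
        sig_v2[q, 1] = t_b[tr]
        sig_v2[q, 2] = t_c[tr]
        sig_d2[q] = t_diam[tr]
        q += 1
    tet_pivots = np.empty(ncand2 + 1, dtype=np.int64)
    nbars, _ = _reduce_dim(
        dm, B, thresh, 2, sig_v2, sig_d2, keep_essential,
        births, deaths, dims, nbars, tet_pivots,
    )
    return births[:nbars], deaths[:nbars], dims[:nbars]


def rips_pairs(dm: np.ndarray, maxdim: int, eps_max: float):
    """Python entry point; see :func:`_rips_pairs`."""
    dm = np.ascontiguousarray(dm, dtype=np.float64)
    return _rips_pairs(dm, maxdim, eps_max)
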
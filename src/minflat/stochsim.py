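"""Event-driven stochastic simulation of the Min reaction network.

The same five-species network integrated by :mod:`minflat.detsim` is treated
as a spatially discrete jump process: integer molecule counts per voxel,
reactions within voxels, and diffusion as per-molecule hops between adjacent
interior voxels at rate ``D/dx^2`` per open face.  Membrane molecules never
hop (the model has no membrane diffusion, which is what produces the "starry
night" pinning of membrane clusters).

Per-voxel event rates follow the deterministic equations with densities
replaced by counts over the actual boundary-voxel interior volume ``v_i``:

* nucleotide exchange         ``n_DADP * k_exchange``
* spontaneous attachment      ``n_DATP * k_D * a_i / v_i``   (membrane voxels)
* cooperative recruitment     ``n_DATP * k_dD * (n_sD + n_sDE) / v_i``
* MinE binding                ``k_E * n_E * n_sD / v_i``
* hydrolysis / release        ``n_sDE * k_de``

Two exact samplers are provided: the next-subvolume method (per-voxel next
event times in an indexed binary heap; the default) and the direct Gillespie
method (linear scan; the correctness reference for small systems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .geometry import CellGeometry
from .params import InitialCondition, RateParameters

__all__ = ["CountState", "CountTrajectory", "voxel_propensities", "simulate"]

# event codes
_EXCHANGE, _ATTACH, _RECRUIT, _EBIND, _HYDROLYSIS = 0, 1, 2, 3, 4


@dataclass
class CountState:
    """Integer molecule counts per voxel (cytoplasmic: MinD:ADP, MinD:ATP,
    MinE; membrane: MinD, MinD:MinE complex)."""

    counts: np.ndarray  # (5, n_voxels) int64, flattened interior order
    time: float


def voxel_propensities(
    counts: np.ndarray, geometry: CellGeometry, params: RateParameters, voxel
) -> list[tuple[str, float]]:
    """Reaction and diffusion event rates (1/s) for one voxel.

    ``counts`` is the (5, n) flattened count array; ``voxel`` is either a
    flat interior index or an (i, j, k) grid index.  Exterior voxels return
    an empty list.
    """
    lat = _lattice(geometry)
    if np.ndim(voxel) > 0 or isinstance(voxel, tuple):
        i = int(lat.flat[tuple(voxel)])
        if i < 0:
            return []
    else:
        i = int(voxel)
    c0, c1, c2, m0, m1 = (int(counts[k, i]) for k in range(5))
    out = []
    if c0:
        out.append(("nucleotide_exchange", c0 * params.k_exchange))
    inv_v = 1.0 / lat.v[i]
    if lat.area[i] > 0:
        if c1 and params.k_D:
            out.append(("attachment", c1 * params.k_D * lat.area[i] * inv_v))
        if c1 and (m0 + m1):
            out.append(("recruitment", c1 * params.k_dD * (m0 + m1) * inv_v))
        if c2 and m0:
            out.append(("mine_binding", params.k_E * c2 * m0 * inv_v))
        if m1:
            out.append(("hydrolysis", m1 * params.k_de))
    hop = (params.D_D, params.D_D, params.D_E)
    for k, (name, n_k) in enumerate(
        (("hop_mind_adp", c0), ("hop_mind_atp", c1), ("hop_mine", c2))
    ):
        for f in range(6):
            if n_k and lat.nbr[i, f] >= 0:
                out.append((name, n_k * hop[k] / lat.dx**2))
    return out


class _StochLattice:
    def __init__(self, geom: CellGeometry):
        idx = np.argwhere(geom.mask)
        self.idx = idx
        self.n = len(idx)
        flat = -np.ones(geom.mask.shape, dtype=np.int64)
        flat[tuple(idx.T)] = np.arange(self.n)
        self.flat = flat
        nbr = -np.ones((self.n, 6), dtype=np.int64)
        for a in range(3):
            for si, s in enumerate((-1, 1)):
                j = idx.copy()
                j[:, a] += s
                ok = (j[:, a] >= 0) & (j[:, a] < geom.mask.shape[a])
                nbr[ok, 2 * a + si] = flat[tuple(j[ok].T)]
        self.nbr = nbr
        self.v = geom.volume[tuple(idx.T)]
        self.area = geom.area[tuple(idx.T)]
        self.dx = geom.dx


_lat_cache: dict[int, _StochLattice] = {}


def _lattice(geom: CellGeometry) -> _StochLattice:
    key = id(geom)
    if key not in _lat_cache:
        _lat_cache.clear()
        _lat_cache[key] = _StochLattice(geom)
    return _lat_cache[key]


@njit(inline="always")
def _voxel_rate(c, m, i, area, inv_v, nopen, dx2, kex, kD, kdD, kde, kE, hop0, hop2):
    r = kex * c[0, i]
    if area[i] > 0.0:
        r += c[1, i] * (kD * area[i] + kdD * (m[0, i] + m[1, i])) * inv_v[i]
        r += kE * c[2, i] * m[0, i] * inv_v[i]
        r += kde * m[1, i]
    r += (hop0 * (c[0, i] + c[1, i]) + hop2 * c[2, i]) * nopen[i]
    return r


@njit(cache=True)
def _heap_swap(heap, pos, a, b):
    va, vb = heap[a], heap[b]
    heap[a], heap[b] = vb, va
    pos[va], pos[vb] = b, a


@njit(cache=True)
def _sift_down(heap, pos, tnext, k):
    n = heap.shape[0]
    while True:
        l = 2 * k + 1
        r = l + 1
        small = k
        if l < n and tnext[heap[l]] < tnext[heap[small]]:
            small = l
        if r < n and tnext[heap[r]] < tnext[heap[small]]:
            small = r
        if small == k:
            return
        _heap_swap(heap, pos, k, small)
        k = small


@njit(cache=True)
def _sift_up(heap, pos, tnext, k):
    while k > 0:
        p = (k - 1) // 2
        if tnext[heap[k]] < tnext[heap[p]]:
            _heap_swap(heap, pos, k, p)
            k = p
        else:
            return


@njit(cache=True)
def _update_voxel(i, t, heap, pos, tnext, rtot, c, m, area, inv_v, nopen, dx2,
                  kex, kD, kdD, kde, kE, hop0, hop2):
    r = _voxel_rate(c, m, i, area, inv_v, nopen, dx2, kex, kD, kdD, kde, kE, hop0, hop2)
    rtot[i] = r
    old = tnext[i]
    if r > 0.0:
        tnext[i] = t + np.random.exponential() / r
    else:
        tnext[i] = np.inf
    k = pos[i]
    if tnext[i] < old:
        _sift_up(heap, pos, tnext, k)
    else:
        _sift_down(heap, pos, tnext, k)


@njit(cache=True)
def _nsm_run(c, m, t0, t_end, seed, nbr, area, inv_v, nopen, dx2,
             kex, kD, kdD, kde, kE, hop0, hop2):
    np.random.seed(seed)
    n = c.shape[1]
    rtot = np.empty(n)
    tnext = np.empty(n)
    heap = np.arange(n)
    pos = np.arange(n)
    for i in range(n):
        r = _voxel_rate(c, m, i, area, inv_v, nopen, dx2, kex, kD, kdD, kde, kE, hop0, hop2)
        rtot[i] = r
        tnext[i] = t0 + np.random.exponential() / r if r > 0.0 else np.inf
    for i in range(n // 2 - 1, -1, -1):
        _sift_down(heap, pos, tnext, i)
    t = t0
    while True:
        v = heap[0]
        t = tnext[v]
        if t >= t_end:
            return t_end
        # choose channel within voxel v
        u = np.random.random() * rtot[v]
        acc = kex * c[0, v]
        other = -1
        if u < acc:
            c[0, v] -= 1
            c[1, v] += 1
        else:
            done = False
            if area[v] > 0.0:
                r_att = c[1, v] * kD * area[v] * inv_v[v]
                r_rec = c[1, v] * kdD * (m[0, v] + m[1, v]) * inv_v[v]
                r_eb = kE * c[2, v] * m[0, v] * inv_v[v]
                r_hyd = kde * m[1, v]
                if u < acc + r_att + r_rec:
                    c[1, v] -= 1
                    m[0, v] += 1
                    done = True
                elif u < acc + r_att + r_rec + r_eb:
                    c[2, v] -= 1
                    m[0, v] -= 1
                    m[1, v] += 1
                    done = True
                elif u < acc + r_att + r_rec + r_eb + r_hyd:
                    m[1, v] -= 1
                    c[0, v] += 1
                    c[2, v] += 1
                    done = True
                acc += r_att + r_rec + r_eb + r_hyd
            if not done:
                # diffusion hop: pick species then face
                u -= acc
                sp = 0
                r_sp = hop0 * c[0, v] * nopen[v]
                if u >= r_sp:
                    u -= r_sp
                    sp = 1
                    r_sp = hop0 * c[1, v] * nopen[v]
                    if u >= r_sp:
                        u -= r_sp
                        sp = 2
                        r_sp = hop2 * c[2, v] * nopen[v]
                per_face = r_sp / nopen[v]
                f = 0
                target = -1
                for f in range(6):
                    j = nbr[v, f]
                    if j >= 0:
                        if u < per_face:
                            target = j
                            break
                        u -= per_face
                if target < 0:  # numerical edge: put in last open face
                    for f in range(5, -1, -1):
                        if nbr[v, f] >= 0:
                            target = nbr[v, f]
                            break
                if target >= 0:
                    c[sp, v] -= 1
                    c[sp, target] += 1
                    other = target
        _update_voxel(v, t, heap, pos, tnext, rtot, c, m, area, inv_v, nopen,
                      dx2, kex, kD, kdD, kde, kE, hop0, hop2)
        if other >= 0:
            _update_voxel(other, t, heap, pos, tnext, rtot, c, m, area, inv_v,
                          nopen, dx2, kex, kD, kdD, kde, kE, hop0, hop2)


@njit(cache=True)
def _direct_run(c, m, t0, t_end, seed, nbr, area, inv_v, nopen, dx2,
                kex, kD, kdD, kde, kE, hop0, hop2):
    """Direct Gillespie: recompute all voxel rates each event (reference)."""
    np.random.seed(seed)
    n = c.shape[1]
    rtot = np.empty(n)
    t = t0
    while True:
        rsum = 0.0
        for i in range(n):
            rtot[i] = _voxel_rate(c, m, i, area, inv_v, nopen, dx2,
                                  kex, kD, kdD, kde, kE, hop0, hop2)
            rsum += rtot[i]
        if rsum <= 0.0:
            return t_end
        t += np.random.exponential() / rsum
        if t >= t_end:
            return t_end
        u = np.random.random() * rsum
        v = 0
        for i in range(n):
            if u < rtot[i]:
                v = i
                break
            u -= rtot[i]
        # same channel logic as NSM, factored crudely to stay jit-simple
        acc = kex * c[0, v]
        if u < acc:
            c[0, v] -= 1
            c[1, v] += 1
            continue
        done = False
        if area[v] > 0.0:
            r_att = c[1, v] * kD * area[v] * inv_v[v]
            r_rec = c[1, v] * kdD * (m[0, v] + m[1, v]) * inv_v[v]
            r_eb = kE * c[2, v] * m[0, v] * inv_v[v]
            r_hyd = kde * m[1, v]
            if u < acc + r_att + r_rec:
                c[1, v] -= 1
                m[0, v] += 1
                done = True
            elif u < acc + r_att + r_rec + r_eb:
                c[2, v] -= 1
                m[0, v] -= 1
                m[1, v] += 1
                done = True
            elif u < acc + r_att + r_rec + r_eb + r_hyd:
                m[1, v] -= 1
                c[0, v] += 1
                c[2, v] += 1
                done = True
            acc += r_att + r_rec + r_eb + r_hyd
        if done:
            continue
        u -= acc
        sp = 0
        r_sp = hop0 * c[0, v] * nopen[v]
        if u >= r_sp:
            u -= r_sp
            sp = 1
            r_sp = hop0 * c[1, v] * nopen[v]
            if u >= r_sp:
                u -= r_sp
                sp = 2
                r_sp = hop2 * c[2, v] * nopen[v]
        per_face = r_sp / nopen[v]
        target = -1
        for f in range(6):
            j = nbr[v, f]
            if j >= 0:
                if u < per_face:
                    target = j
                    break
                u -= per_face
        if target < 0:
            for f in range(5, -1, -1):
                if nbr[v, f] >= 0:
                    target = nbr[v, f]
                    break
        if target >= 0:
            c[sp, v] -= 1
            c[sp, target] += 1


class _CountSnap:
    """Lazy density view of one stored count snapshot (densities reproduce
    the exact integer counts when re-weighted by voxel volume/area)."""

    __slots__ = ("_lat", "_geom", "_data", "time")

    def __init__(self, lat, geom, data, time):
        self._lat = lat
        self._geom = geom
        self._data = data
        self.time = time

    def _cyt(self, k):
        out = np.zeros(self._geom.mask.shape)
        out[tuple(self._lat.idx.T)] = self._data[k] / self._lat.v
        return out

    def _mem(self, k):
        out = np.zeros(self._geom.mask.shape)
        a = np.where(self._lat.area > 0, self._lat.area, 1.0)
        out[tuple(self._lat.idx.T)] = self._data[k] / a
        return out

    @property
    def rho_dadp(self):
        return self._cyt(0)

    @property
    def rho_datp(self):
        return self._cyt(1)

    @property
    def rho_e(self):
        return self._cyt(2)

    @property
    def sigma_d(self):
        return self._mem(3)

    @property
    def sigma_de(self):
        return self._mem(4)


@dataclass
class CountTrajectory:
    geometry: CellGeometry
    times: np.ndarray
    data: np.ndarray = field(repr=False)  # (n_snap, 5, n) int64
    seed: int = 0
    _lat: _StochLattice = field(repr=False, default=None)

    def __len__(self):
        return len(self.times)

    def __getitem__(self, i):
        return _CountSnap(self._lat, self.geometry, self.data[i], self.times[i])

    def __iter__(self):
        for i in range(len(self.times)):
            yield self[i]

    def totals(self, i: int) -> tuple[int, int]:
        d = self.data[i]
        return int(d[0].sum() + d[1].sum() + d[3].sum() + d[4].sum()), int(
            d[2].sum() + d[4].sum()
        )


def initial_counts(
    geometry: CellGeometry, init: InitialCondition, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial scatter of the rounded protein totals over interior voxels
    proportionally to voxel volume; all MinD starts as cytoplasmic MinD:ADP
    and all MinE cytoplasmic."""
    lat = _lattice(geometry)
    p = lat.v / lat.v.sum()
    n_d = int(round(init.mind * geometry.total_volume))
    n_e = int(round(init.mine * geometry.total_volume))
    counts = np.zeros((5, lat.n), dtype=np.int64)
    counts[0] = rng.multinomial(n_d, p)
    counts[2] = rng.multinomial(n_e, p)
    return counts


def simulate(
    geometry: CellGeometry,
    params: RateParameters,
    init: InitialCondition,
    t_end: float,
    seed: int = 0,
    output_stride: float = 1.0,
    method: str = "nsm",
    counts0: np.ndarray | None = None,
) -> CountTrajectory:
    """Exact stochastic trajectory, with snapshots every ``output_stride``.

    ``method`` selects the next-subvolume sampler ("nsm", default) or the
    direct method ("direct"); both sample the same jump process.
    """
    if method not in ("nsm", "direct"):
        raise ValueError("method must be 'nsm' or 'direct'")
    lat = _lattice(geometry)
    rng = np.random.default_rng(seed)
    counts = (
        counts0.astype(np.int64).copy()
        if counts0 is not None
        else initial_counts(geometry, init, rng)
    )
    c = counts[:3].copy()
    m = counts[3:].copy()
    nopen = (lat.nbr >= 0).sum(axis=1).astype(np.float64)
    inv_v = 1.0 / lat.v
    dx2 = lat.dx**2
    hop0 = params.D_D / dx2
    hop2 = params.D_E / dx2

    n_out = int(np.floor(t_end / output_stride + 1e-9)) + 1
    data = np.empty((n_out, 5, lat.n), dtype=np.int64)
    times = np.empty(n_out)
    data[0, :3] = c
    data[0, 3:] = m
    times[0] = 0.0
    runner = _nsm_run if method == "nsm" else _direct_run
    t = 0.0
    for i in range(1, n_out):
        target = i * output_stride
        sub_seed = int(rng.integers(0, 2**31 - 1))
        t = runner(
            c, m, t, target, sub_seed, lat.nbr, lat.area, inv_v, nopen, dx2,
            params.k_exchange, params.k_D, params.k_dD, params.k_de, params.k_E,
            hop0, hop2,
        )
        data[i, :3] = c
        data[i, 3:] = m
        times[i] = t
        if c.min() < 0 or m.min() < 0:
            raise RuntimeError("negative molecule count: stochastic sampler bug")
    return CountTrajectory(geometry, times, data, seed, lat)
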
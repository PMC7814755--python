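"""Global tractography by simulated annealing over a segment configuration.

Rather than walking streamlines locally, the tracker fits a whole set of short
oriented segments ("polymer" pieces) to the diffusion data at once. The energy
has a data term - the squared residual between the measured anisotropy
contrast (direction-dependent part of the attenuation) and the superposition
of per-segment stick kernels deposited with trilinear weights - and an
internal term that charges free segment endpoints, rewards links, and
penalizes bending across links. A Metropolis-Hastings chain over proposals
{birth, death, move/rotate, link, unlink} with geometric cooling minimizes the
energy; after cooling, the state is reheated and re-iterated several rounds,
and the streamlines extracted from each round are accumulated into one final
tractogram, which markedly improves retest reliability of the recovered
connections. Linked segments are chained into polylines; orientations are
sign-free and chains may be traversed in either direction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bundles import Tractogram
from .gradients import GradientScheme

_CORNERS = np.array(list(itertools.product((0, 1), repeat=3)))


@dataclass
class Segment:
    """One oriented segment: center (world mm), sign-free unit orientation,
    half length (mm), and an optional link id at each end (0: minus, 1: plus)."""

    center: np.ndarray
    orientation: np.ndarray
    half_length: float
    links: list = field(default_factory=lambda: [None, None])

    def endpoint(self, end: int) -> np.ndarray:
        s = 1.0 if end == 1 else -1.0
        return self.center + s * self.half_length * self.orientation


@dataclass(frozen=True)
class AnnealSchedule:
    """Cooling and accumulation schedule.

    The reheat temperature 0.1 and the five accumulation rounds follow the
    source strategy; iteration counts are desk-scale defaults (the original
    10^7 iterations per round is a cluster-scale setting of the same
    architecture).
    """

    t_start: float = 0.1
    t_end: float = 0.001
    n_iter: int = 200_000
    reheat_t: float = 0.1
    reheat_iter: int = 50_000
    rounds: int = 5

    def __post_init__(self):
        if not (self.t_start >= self.t_end > 0):
            raise ValueError("need t_start >= t_end > 0")
        if self.rounds < 1:
            raise ValueError("need at least one accumulation round")


@dataclass(frozen=True)
class EnergyModel:
    """Weights of the energy functional (data term + internal term).

    ``kernel_weight`` scales the per-segment stick deposit; the endpoint
    penalty / link bonus / curvature triplet shapes chain formation. These are
    surrogate constants exposed as configuration: the original toolbox's
    preset values are not public.
    """

    d_a: float = 2.0                 # stick diffusivity of the kernel, um^2/ms
    kernel_weight: float = 0.5
    lambda_internal: float = 1.0
    endpoint_penalty: float = 0.15
    link_bonus: float = 0.30
    curvature_weight: float = 0.30
    segment_potential: float = 1.0   # per-segment cost (point-process prior)
    link_radius_mm: float = 2.25     # max endpoint distance for a link
    max_link_angle_deg: float = 60.0
    half_length_factor: float = 0.67  # half length = factor * voxel size


@dataclass(frozen=True)
class ProposalWeights:
    birth: float = 0.12
    death: float = 0.12
    move: float = 0.24
    link: float = 0.10
    unlink: float = 0.10
    extend: float = 0.16   # birth of a segment linked to a free endpoint
    retract: float = 0.16  # removal of a chain-end segment together with its link


class _IndexedSet:
    """Set with O(1) uniform sampling (list + position map, swap-remove)."""

    def __init__(self):
        self.items = []
        self.pos = {}

    def add(self, x):
        if x not in self.pos:
            self.pos[x] = len(self.items)
            self.items.append(x)

    def discard(self, x):
        i = self.pos.pop(x, None)
        if i is None:
            return
        last = self.items.pop()
        if i < len(self.items):
            self.items[i] = last
            self.pos[last] = i

    def sample(self, rng):
        return self.items[rng.integers(len(self.items))]

    def __len__(self):
        return len(self.items)

    def __contains__(self, x):
        return x in self.pos

    def __iter__(self):
        return iter(self.items)


@dataclass
class SegmentState:
    """A segment configuration: segments by id plus links ((sid, end), (sid, end))."""

    segments: dict
    links: dict
    half_length: float

    def n_links(self) -> int:
        return len(self.links)

    def n_free_endpoints(self) -> int:
        return 2 * len(self.segments) - 2 * len(self.links)

    def internal_energy(self, model: EnergyModel) -> float:
        curv = 0.0
        for (sa, ea), (sb, eb) in self.links.values():
            na = self.segments[sa].orientation
            nb = self.segments[sb].orientation
            curv += 1.0 - abs(float(np.dot(na, nb)))
        return (model.segment_potential * len(self.segments)
                + model.endpoint_penalty * self.n_free_endpoints()
                - model.link_bonus * self.n_links()
                + model.curvature_weight * curv)


def _measured_contrast(dwi: np.ndarray, scheme: GradientScheme, support_idx: np.ndarray):
    """Anisotropy contrast per support voxel: b0-normalized attenuation on the
    weighted volumes minus its per-shell mean (zero for isotropic signals)."""
    vox = dwi[tuple(support_idx.T)]
    b0 = vox[:, scheme.volumes_in_shell(0)].mean(axis=1)
    b0 = np.where(b0 > 0, b0, np.inf)
    weighted = np.flatnonzero(scheme.shell_ids != 0)
    att = vox[:, weighted] / b0[:, None]
    shells = scheme.shell_ids[weighted]
    for s in np.unique(shells):
        m = shells == s
        att[:, m] -= att[:, m].mean(axis=1, keepdims=True)
    return att, weighted


class _Chain:
    """Incremental Metropolis-Hastings sampler over segment configurations."""

    def __init__(self, dwi, scheme, mask, affine=None, model=None,
                 proposal_weights=None, seed=0):
        self.model = model or EnergyModel()
        self.pw = proposal_weights or ProposalWeights()
        w = np.array([self.pw.birth, self.pw.death, self.pw.move,
                      self.pw.link, self.pw.unlink, self.pw.extend,
                      self.pw.retract], dtype=float)
        self._cum = np.cumsum(w / w.sum())
        self.rng = np.random.default_rng(seed)
        self.scheme = scheme
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty tracking mask")
        self.mask = mask
        self.shape_arr = np.array(mask.shape)
        self.affine = np.diag([1.5, 1.5, 1.5, 1.0]) if affine is None else np.asarray(affine, float)
        inv = np.linalg.inv(self.affine)
        self.inv3 = inv[:3, :3].copy()
        self.invt = inv[:3, 3].copy()
        self.voxel_size = float(np.linalg.norm(self.affine[:3, :3], axis=0).mean())
        self.half_length = self.model.half_length_factor * self.voxel_size

        support = ndimage.binary_dilation(mask, iterations=1)
        self.support_idx = np.argwhere(support)
        self.rowmap = -np.ones(mask.shape, dtype=int)
        self.rowmap[tuple(self.support_idx.T)] = np.arange(len(self.support_idx))
        self.mask_idx = np.argwhere(mask)
        self.n_mask = len(self.mask_idx)
        # reference measure of the birth proposal: uniform over mask volume x half-sphere
        self.birth_measure = self.n_mask * self.voxel_size**3 * 2.0 * np.pi

        self.meas, weighted = _measured_contrast(dwi, scheme, self.support_idx)
        self.bw = scheme.bvalues[weighted]
        self.gw = scheme.directions[weighted]
        sh = scheme.shell_ids[weighted]
        # projection removing per-shell means: k_centered = P k
        nw = len(weighted)
        P = np.eye(nw)
        for s in np.unique(sh):
            g = np.flatnonzero(sh == s)
            P[np.ix_(g, g)] -= 1.0 / len(g)
        self._proj = P * self.model.kernel_weight

        self.R = self.meas.copy()
        self.e_data = float((self.R**2).sum())
        self.e_int = 0.0

        self.segments: dict[int, Segment] = {}
        self.links: dict[int, tuple] = {}
        self.seg_ids = _IndexedSet()
        self.link_ids = _IndexedSet()
        self.unlinked = _IndexedSet()
        self.terminal = _IndexedSet()   # segments linked at exactly one end
        self.free_set = _IndexedSet()   # (sid, end) tuples
        self._ep_cache = None           # lazily built arrays for candidate search
        self._next_sid = 0
        self._next_lid = 0
        self.cos_link = np.cos(np.deg2rad(self.model.max_link_angle_deg))
        # extension proposal reference measure: ball around the endpoint for the
        # entry point x orientation cap within the bending limit
        r = self.model.link_radius_mm
        self.ext_measure = (4.0 / 3.0) * np.pi * r**3 * 2.0 * np.pi * (1.0 - self.cos_link)
        self.n_accept = 0
        self.n_prop = 0

    # -- energy pieces ------------------------------------------------------

    def kernel(self, orientation: np.ndarray) -> np.ndarray:
        """Mean-removed stick kernel on the weighted volumes, scaled by the deposit weight."""
        c2 = (self.gw @ orientation) ** 2
        return self._proj @ np.exp(-self.bw * self.model.d_a * c2)

    def _tri(self, center: np.ndarray):
        """Trilinear rows and weights of a deposit at ``center`` (support rows only)."""
        v = self.inv3 @ center + self.invt
        base = np.floor(v).astype(int)
        frac = v - base
        idx = base + _CORNERS
        wts = np.prod(np.where(_CORNERS == 1, frac, 1.0 - frac), axis=1)
        ok = np.all((idx >= 0) & (idx < self.shape_arr), axis=1)
        rows = np.full(8, -1, dtype=int)
        if ok.any():
            rows[ok] = self.rowmap[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        good = rows >= 0
        return rows[good], wts[good]

    def _in_mask(self, center: np.ndarray) -> bool:
        v = self.inv3 @ center + self.invt
        ijk = np.rint(v).astype(int)
        if np.any(ijk < 0) or np.any(ijk >= self.shape_arr):
            return False
        return bool(self.mask[ijk[0], ijk[1], ijk[2]])

    def _delta_add(self, rows, wts, k) -> float:
        """Energy change of adding contribution w_i * k to residual rows."""
        return float(-2.0 * (wts * (self.R[rows] @ k)).sum() + (wts**2).sum() * (k @ k))

    # -- free-endpoint candidate search -------------------------------------

    def _eps_arrays(self):
        if self._ep_cache is None:
            eps = self.free_set.items
            if eps:
                pos = np.array([self.segments[s].endpoint(e) for s, e in eps])
                ori = np.array([self.segments[s].orientation for s, e in eps])
                cen = np.array([self.segments[s].center for s, e in eps])
                out = np.array([(1.0 if e == 1 else -1.0) for s, e in eps])[:, None] * ori
                sid = np.array([s for s, e in eps])
            else:
                pos = np.zeros((0, 3))
                ori = np.zeros((0, 3))
                cen = np.zeros((0, 3))
                out = np.zeros((0, 3))
                sid = np.zeros(0, dtype=int)
            self._ep_cache = (list(eps), pos, ori, cen, out, sid)
        return self._ep_cache

    def _candidates(self, ep: tuple) -> list:
        """Admissible link partners for a free endpoint: within the link radius,
        aligned within the bending limit, and continuing outward (the partner
        segment lies beyond this endpoint and vice versa - chains cannot fold
        back onto themselves)."""
        eps, pos, ori, cen, out, sid = self._eps_arrays()
        s0, e0 = ep
        seg0 = self.segments[s0]
        p0 = seg0.endpoint(e0)
        n0 = seg0.orientation
        c0 = seg0.center
        out0 = (1.0 if e0 == 1 else -1.0) * n0
        d2 = ((pos - p0) ** 2).sum(axis=1)
        fwd = ((cen - c0) @ out0 > 0) & (((c0 - cen) * out).sum(axis=1) > 0)
        ok = ((d2 <= self.model.link_radius_mm**2)
              & (np.abs(ori @ n0) >= self.cos_link) & (sid != s0) & fwd)
        return [eps[i] for i in np.flatnonzero(ok)]

    def _curv(self, sid_a, sid_b) -> float:
        return 1.0 - abs(float(self.segments[sid_a].orientation @ self.segments[sid_b].orientation))

    # -- proposals ----------------------------------------------------------

    def _accept(self, log_ratio: float) -> bool:
        if log_ratio >= 0:
            return True
        return self.rng.random() < np.exp(log_ratio)

    def _random_orientation(self) -> np.ndarray:
        n = self.rng.standard_normal(3)
        n /= np.linalg.norm(n)
        return n if n[2] >= 0 else -n  # half-sphere; orientations are sign-free

    def step(self, T: float):
        self.n_prop += 1
        kind = int(np.searchsorted(self._cum, self.rng.random()))
        if kind == 0:
            self._propose_birth(T)
        elif kind == 1:
            self._propose_death(T)
        elif kind == 2:
            self._propose_move(T)
        elif kind == 3:
            self._propose_link(T)
        elif kind == 4:
            self._propose_unlink(T)
        elif kind == 5:
            self._propose_extend(T)
        else:
            self._propose_retract(T)

    def _sync_linkage(self, sid):
        """Refresh unlinked/terminal membership from the segment's link count."""
        n = sum(l is not None for l in self.segments[sid].links)
        if n == 0:
            self.unlinked.add(sid)
            self.terminal.discard(sid)
        elif n == 1:
            self.unlinked.discard(sid)
            self.terminal.add(sid)
        else:
            self.unlinked.discard(sid)
            self.terminal.discard(sid)

    def _propose_birth(self, T):
        vox = self.mask_idx[self.rng.integers(self.n_mask)]
        offs = self.rng.uniform(-0.5, 0.5, 3)
        center = self.affine[:3, :3] @ (vox + offs) + self.affine[:3, 3]
        orient = self._random_orientation()
        rows, wts = self._tri(center)
        k = self.kernel(orient)
        d_data = self._delta_add(rows, wts, k)
        d_int = 2.0 * self.model.endpoint_penalty + self.model.segment_potential
        n_unl_after = len(self.unlinked) + 1
        log_ratio = (-(d_data + self.model.lambda_internal * d_int) / T
                     + np.log(self.pw.death * self.birth_measure
                              / (self.pw.birth * n_unl_after)))
        if self._accept(log_ratio):
            sid = self._next_sid
            self._next_sid += 1
            seg = Segment(center=center, orientation=orient, half_length=self.half_length)
            self.segments[sid] = seg
            self.seg_ids.add(sid)
            self.unlinked.add(sid)
            self.free_set.add((sid, 0))
            self.free_set.add((sid, 1))
            self._ep_cache = None
            self.R[rows] -= wts[:, None] * k
            self.e_data += d_data
            self.e_int += d_int
            self.n_accept += 1

    def _propose_death(self, T):
        if not len(self.unlinked):
            return
        sid = self.unlinked.sample(self.rng)
        seg = self.segments[sid]
        rows, wts = self._tri(seg.center)
        k = self.kernel(seg.orientation)
        d_data = float(2.0 * (wts * (self.R[rows] @ k)).sum() + (wts**2).sum() * (k @ k))
        d_int = -2.0 * self.model.endpoint_penalty - self.model.segment_potential
        log_ratio = (-(d_data + self.model.lambda_internal * d_int) / T
                     + np.log(self.pw.birth * len(self.unlinked)
                              / (self.pw.death * self.birth_measure)))
        if self._accept(log_ratio):
            self.R[rows] += wts[:, None] * k
            self.e_data += d_data
            self.e_int += d_int
            del self.segments[sid]
            self.seg_ids.discard(sid)
            self.unlinked.discard(sid)
            self.terminal.discard(sid)
            self.free_set.discard((sid, 0))
            self.free_set.discard((sid, 1))
            self._ep_cache = None
            self.n_accept += 1

    def _propose_move(self, T):
        if not len(self.seg_ids):
            return
        sid = self.seg_ids.sample(self.rng)
        seg = self.segments[sid]
        # temperature-scaled symmetric steps: coarse early, refining late
        scale = np.sqrt(T / 0.1)
        new_center = seg.center + self.rng.normal(0.0, 0.3 * self.voxel_size * scale, 3)
        ax = self.rng.standard_normal(3)
        ax -= (ax @ seg.orientation) * seg.orientation
        nax = np.linalg.norm(ax)
        ang = self.rng.normal(0.0, np.deg2rad(20.0) * scale)
        if nax > 0:
            ax /= nax
            new_orient = np.cos(ang) * seg.orientation + np.sin(ang) * ax
            new_orient /= np.linalg.norm(new_orient)
        else:
            new_orient = seg.orientation
        if not self._in_mask(new_center):
            return
        trial = Segment(center=new_center, orientation=new_orient,
                        half_length=seg.half_length, links=seg.links)
        d_curv = 0.0
        for end in (0, 1):
            lid = seg.links[end]
            if lid is None:
                continue
            (sa, ea), (sb, eb) = self.links[lid]
            osid, oend = (sb, eb) if sa == sid else (sa, ea)
            other = self.segments[osid]
            if np.linalg.norm(trial.endpoint(end) - other.endpoint(oend)) > self.model.link_radius_mm:
                return
            cos_new = abs(float(new_orient @ other.orientation))
            if cos_new < self.cos_link:
                return
            out_new = (1.0 if end == 1 else -1.0) * new_orient
            out_oth = (1.0 if oend == 1 else -1.0) * other.orientation
            if ((other.center - new_center) @ out_new <= 0
                    or (new_center - other.center) @ out_oth <= 0):
                return
            d_curv += (1.0 - cos_new) - self._curv(sid, osid)

        rows_o, wts_o = self._tri(seg.center)
        k_o = self.kernel(seg.orientation)
        rows_n, wts_n = self._tri(new_center)
        k_n = self.kernel(new_orient)
        union = np.unique(np.concatenate([rows_o, rows_n]))
        local = self.R[union].copy()
        pos = {r: i for i, r in enumerate(union)}
        e0 = float((local**2).sum())
        local[[pos[r] for r in rows_o]] += wts_o[:, None] * k_o
        local[[pos[r] for r in rows_n]] -= wts_n[:, None] * k_n
        d_data = float((local**2).sum()) - e0
        d_int = self.model.curvature_weight * d_curv
        if self._accept(-(d_data + self.model.lambda_internal * d_int) / T):
            self.R[union] = local
            self.e_data += d_data
            self.e_int += d_int
            seg.center = new_center
            seg.orientation = new_orient
            self._ep_cache = None
            self.n_accept += 1

    def _link_pair_q(self, ep1, ep2) -> float:
        """Forward proposal probability of creating link {ep1, ep2}."""
        n_free = len(self.free_set)
        if n_free == 0:
            return 0.0
        k1 = len(self._candidates(ep1))
        k2 = len(self._candidates(ep2))
        q = 0.0
        if k1 > 0:
            q += 1.0 / (n_free * k1)
        if k2 > 0:
            q += 1.0 / (n_free * k2)
        return self.pw.link * q

    def _propose_link(self, T):
        if not len(self.free_set):
            return
        ep1 = self.free_set.sample(self.rng)
        cands = self._candidates(ep1)
        if not cands:
            return
        ep2 = cands[self.rng.integers(len(cands))]
        q_fwd = self._link_pair_q(ep1, ep2)
        q_rev = self.pw.unlink / (len(self.links) + 1)
        (sa, ea), (sb, eb) = ep1, ep2
        d_int = (-self.model.link_bonus - 2.0 * self.model.endpoint_penalty
                 + self.model.curvature_weight * self._curv(sa, sb))
        log_ratio = -(self.model.lambda_internal * d_int) / T + np.log(q_rev / q_fwd)
        if self._accept(log_ratio):
            lid = self._next_lid
            self._next_lid += 1
            self.links[lid] = (ep1, ep2)
            self.link_ids.add(lid)
            self.segments[sa].links[ea] = lid
            self.segments[sb].links[eb] = lid
            self._sync_linkage(sa)
            self._sync_linkage(sb)
            self.free_set.discard(ep1)
            self.free_set.discard(ep2)
            self._ep_cache = None
            self.e_int += d_int
            self.n_accept += 1

    def _propose_unlink(self, T):
        if not len(self.links):
            return
        lid = self.link_ids.sample(self.rng)
        (sa, ea), (sb, eb) = self.links[lid]
        q_fwd = self.pw.unlink / len(self.links)
        d_int = (self.model.link_bonus + 2.0 * self.model.endpoint_penalty
                 - self.model.curvature_weight * self._curv(sa, sb))
        # reverse probability: re-creating this link once both endpoints are free
        self.free_set.add((sa, ea))
        self.free_set.add((sb, eb))
        self._ep_cache = None
        del self.links[lid]
        self.link_ids.discard(lid)
        self.segments[sa].links[ea] = None
        self.segments[sb].links[eb] = None
        q_rev = self._link_pair_q((sa, ea), (sb, eb))
        log_ratio = (-(self.model.lambda_internal * d_int) / T + np.log(q_rev / q_fwd)
                     if q_rev > 0 else -np.inf)
        if self._accept(log_ratio):
            self.e_int += d_int
            self._sync_linkage(sa)
            self._sync_linkage(sb)
            self.n_accept += 1
        else:  # roll back
            self.links[lid] = ((sa, ea), (sb, eb))
            self.link_ids.add(lid)
            self.segments[sa].links[ea] = lid
            self.segments[sb].links[eb] = lid
            self.free_set.discard((sa, ea))
            self.free_set.discard((sb, eb))
            self._ep_cache = None

    def _propose_extend(self, T):
        """Grow a chain: birth of a segment immediately linked to a free endpoint.

        The entry endpoint is sampled uniformly in the link-radius ball around
        the chosen free endpoint and the orientation uniformly in the bending
        cone, so every admissible terminal-link geometry has positive proposal
        density and the reverse (retract) move stays available after local
        refinements."""
        if not len(self.free_set):
            return
        ep = self.free_set.sample(self.rng)
        sid0, e0 = ep
        seg0 = self.segments[sid0]
        out0 = (1.0 if e0 == 1 else -1.0) * seg0.orientation
        # entry point uniform in the ball, orientation uniform in the cap
        while True:
            u = self.rng.uniform(-1.0, 1.0, 3)
            if (u @ u) <= 1.0:
                break
        entry = seg0.endpoint(e0) + self.model.link_radius_mm * u
        cosang = self.rng.uniform(self.cos_link, 1.0)
        phi = self.rng.uniform(0.0, 2.0 * np.pi)
        e1 = np.array([1.0, 0.0, 0.0])
        if abs(out0[0]) > 0.9:
            e1 = np.array([0.0, 1.0, 0.0])
        e1 = e1 - (e1 @ out0) * out0
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(out0, e1)
        sinang = np.sqrt(max(0.0, 1.0 - cosang**2))
        dirn = cosang * out0 + sinang * (np.cos(phi) * e1 + np.sin(phi) * e2)
        center = entry + self.half_length * dirn
        if not self._in_mask(center):
            return
        # the new link must satisfy the same admissibility as plain link moves
        if ((center - seg0.center) @ out0 <= 0
                or (seg0.center - center) @ (-dirn) <= 0):
            return
        rows, wts = self._tri(center)
        k = self.kernel(dirn)
        d_data = self._delta_add(rows, wts, k)
        curv = 1.0 - abs(float(dirn @ seg0.orientation))
        d_int = (self.model.segment_potential - self.model.link_bonus
                 + self.model.curvature_weight * curv)
        n_links0 = sum(l is not None for l in seg0.links)
        n_term_after = len(self.terminal) + 1 + (1 if n_links0 == 0 else -1)
        log_ratio = (-(d_data + self.model.lambda_internal * d_int) / T
                     + np.log(self.pw.retract * len(self.free_set) * self.ext_measure
                              / (self.pw.extend * max(n_term_after, 1))))
        if self._accept(log_ratio):
            sid = self._next_sid
            self._next_sid += 1
            seg = Segment(center=center, orientation=dirn, half_length=self.half_length)
            self.segments[sid] = seg
            self.seg_ids.add(sid)
            lid = self._next_lid
            self._next_lid += 1
            self.links[lid] = (ep, (sid, 0))
            self.link_ids.add(lid)
            seg.links[0] = lid
            seg0.links[e0] = lid
            self.free_set.discard(ep)
            self.free_set.add((sid, 1))
            self._sync_linkage(sid0)
            self._sync_linkage(sid)
            self._ep_cache = None
            self.R[rows] -= wts[:, None] * k
            self.e_data += d_data
            self.e_int += d_int
            self.n_accept += 1

    def _propose_retract(self, T):
        """Shrink a chain: remove a terminal segment together with its link."""
        if not len(self.terminal):
            return
        sid = self.terminal.sample(self.rng)
        seg = self.segments[sid]
        end = 0 if seg.links[0] is not None else 1
        lid = seg.links[end]
        (sa, ea), (sb, eb) = self.links[lid]
        psid, pend = (sb, eb) if sa == sid else (sa, ea)
        pseg = self.segments[psid]
        # reverse (extend) density must be positive for the current geometry
        pep = pseg.endpoint(pend)
        if np.linalg.norm(seg.endpoint(end) - pep) > self.model.link_radius_mm:
            return
        rows, wts = self._tri(seg.center)
        k = self.kernel(seg.orientation)
        d_data = float(2.0 * (wts * (self.R[rows] @ k)).sum() + (wts**2).sum() * (k @ k))
        curv = self._curv(sid, psid)
        d_int = (-self.model.segment_potential + self.model.link_bonus
                 - self.model.curvature_weight * curv)
        # free endpoints: the segment's free end disappears, the partner's is freed
        n_free_after = len(self.free_set)
        log_ratio = (-(d_data + self.model.lambda_internal * d_int) / T
                     + np.log(self.pw.extend * len(self.terminal)
                              / (self.pw.retract * n_free_after * self.ext_measure)))
        if self._accept(log_ratio):
            self.R[rows] += wts[:, None] * k
            self.e_data += d_data
            self.e_int += d_int
            del self.links[lid]
            self.link_ids.discard(lid)
            pseg.links[pend] = None
            del self.segments[sid]
            self.seg_ids.discard(sid)
            self.terminal.discard(sid)
            self.unlinked.discard(sid)
            self.free_set.discard((sid, 0))
            self.free_set.discard((sid, 1))
            self.free_set.add((psid, pend))
            self._sync_linkage(psid)
            self._ep_cache = None
            self.n_accept += 1

    def insert_segment(self, center, orientation) -> int:
        """Insert a segment unconditionally (tests and warm starts)."""
        center = np.asarray(center, dtype=float)
        orientation = np.asarray(orientation, dtype=float)
        orientation = orientation / np.linalg.norm(orientation)
        rows, wts = self._tri(center)
        k = self.kernel(orientation)
        d_data = self._delta_add(rows, wts, k)
        sid = self._next_sid
        self._next_sid += 1
        seg = Segment(center=center, orientation=orientation, half_length=self.half_length)
        self.segments[sid] = seg
        self.seg_ids.add(sid)
        self.unlinked.add(sid)
        self.free_set.add((sid, 0))
        self.free_set.add((sid, 1))
        self._ep_cache = None
        self.R[rows] -= wts[:, None] * k
        self.e_data += d_data
        self.e_int += 2.0 * self.model.endpoint_penalty + self.model.segment_potential
        return sid

    # -- schedules ----------------------------------------------------------

    def run_cooling(self, t_start, t_end, n_iter):
        if n_iter <= 0:
            return
        temps = t_start * (t_end / t_start) ** (np.arange(n_iter) / max(n_iter - 1, 1))
        for T in temps:
            self.step(float(T))

    @property
    def energy(self) -> float:
        return self.e_data + self.model.lambda_internal * self.e_int

    def state(self) -> SegmentState:
        segs = {sid: Segment(center=s.center.copy(), orientation=s.orientation.copy(),
                             half_length=s.half_length, links=list(s.links))
                for sid, s in self.segments.items()}
        return SegmentState(segments=segs, links=dict(self.links),
                            half_length=self.half_length)


def energy(state: SegmentState, dwi, scheme, mask, affine=None,
           model: EnergyModel | None = None) -> float:
    """Total energy of a segment configuration, computed from scratch."""
    model = model or EnergyModel()
    chain = _Chain(dwi, scheme, mask, affine=affine, model=model, seed=0)
    pred = np.zeros_like(chain.meas)
    for s in state.segments.values():
        rows, wts = chain._tri(s.center)
        pred[rows] += wts[:, None] * chain.kernel(s.orientation)
    e_data = float(((chain.meas - pred) ** 2).sum())
    return e_data + model.lambda_internal * state.internal_energy(model)


def anneal(dwi, scheme, mask, schedule: AnnealSchedule | None = None, seed: int = 0,
           model: EnergyModel | None = None, affine=None,
           proposal_weights: ProposalWeights | None = None,
           return_trace: bool = False):
    """Fit a segment configuration by simulated annealing (single cooling run)."""
    schedule = schedule or AnnealSchedule()
    chain = _Chain(dwi, scheme, mask, affine=affine, model=model,
                   proposal_weights=proposal_weights, seed=seed)
    e0 = chain.energy
    chain.run_cooling(schedule.t_start, schedule.t_end, schedule.n_iter)
    if return_trace:
        return chain.state(), (e0, chain.energy)
    return chain.state()


def accumulate(dwi, scheme, mask, schedule: AnnealSchedule | None = None, seed: int = 0,
               model: EnergyModel | None = None, affine=None,
               min_points: int = 3, return_state: bool = False):
    """Cool once, then reheat-and-extract over several rounds; concatenate.

    With r rounds the streamline count is exactly the sum of per-round counts
    (about r times a single round on stable data).
    """
    schedule = schedule or AnnealSchedule()
    chain = _Chain(dwi, scheme, mask, affine=affine, model=model, seed=seed)
    chain.run_cooling(schedule.t_start, schedule.t_end, schedule.n_iter)
    streamlines = []
    for rnd in range(schedule.rounds):
        if rnd > 0:
            chain.run_cooling(schedule.reheat_t, schedule.t_end, schedule.reheat_iter)
        t = extract_streamlines(chain.state(), min_points=min_points)
        streamlines.extend(t.streamlines)
    out = Tractogram(streamlines, affine=chain.affine)
    if return_state:
        return out, chain.state()
    return out


def extract_streamlines(state: SegmentState, min_points: int = 3) -> Tractogram:
    """Chain linked segments into polylines.

    Each maximal chain of k linked segments becomes a polyline of k+1 points:
    the outer free endpoints plus, at every link, the midpoint of the two
    linked endpoints. Chains with fewer than ``min_points`` points are
    dropped; cycles are broken at an arbitrary link with a warning.
    """
    segs = state.segments
    links = state.links
    visited = set()
    lines = []
    broke_cycle = False

    def walk(sid, entry_end):
        pts = [segs[sid].endpoint(entry_end)]
        while True:
            visited.add(sid)
            exit_end = 1 - entry_end
            lid = segs[sid].links[exit_end]
            if lid is None:
                pts.append(segs[sid].endpoint(exit_end))
                return pts
            (sa, ea), (sb, eb) = links[lid]
            nsid, nend = (sb, eb) if sa == sid else (sa, ea)
            mid = 0.5 * (segs[sid].endpoint(exit_end) + segs[nsid].endpoint(nend))
            pts.append(mid)
            if nsid in visited:  # cycle closed
                return pts
            sid, entry_end = nsid, nend

    for sid, s in segs.items():
        if sid in visited:
            continue
        if s.links[0] is None and s.links[1] is None:
            visited.add(sid)  # an isolated segment is not a chain
            continue
        for end in (0, 1):
            if s.links[end] is None and sid not in visited:
                lines.append(walk(sid, end))
    for sid in segs:
        if sid not in visited:
            broke_cycle = True
            lines.append(walk(sid, 0))
    if broke_cycle:
        warnings.warn("cyclic segment chain broken at an arbitrary link")

    keep = [np.array(p) for p in lines if len(p) >= max(min_points, 2)]
    return Tractogram(keep)
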
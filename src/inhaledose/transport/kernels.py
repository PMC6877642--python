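"""Numba kernels for photon and electron transport in a voxel grid.

Photons use Woodcock (delta) tracking against a per-energy majorant cross
section: flight distances are sampled from the majorant, tentative
collisions are accepted as real with probability μ(voxel, E)/μ_majorant(E),
and every tentative collision scores the delta-collision fluence estimator
1/(μ_majorant·V).  Real collisions split photoelectric (full local
deposit) vs Compton (Klein–Nishina energy–angle sampling by Kahn's
rejection method, the transferred energy deposited at the collision
voxel).  Photons below the cutoff deposit locally; photons leaving the
grid are scored as escaped, so emitted = deposited + escaped holds per
batch to accumulator precision.

Electrons use a condensed-history scheme: continuous slowing down on
tabulated collision stopping power with fractional-energy steps capped at
half a voxel, energy deposited in the voxel where each step starts, and a
Highland/Rayleigh multiple-scattering deflection per step.

Randomness is a counter-based splitmix64 stream keyed on
(seed, batch, history), so every history is an independent reproducible
stream regardless of execution order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_GOLDEN = U64(0x9E3779B97F4A7C15)
_MIX1 = U64(0xBF58476D1CE4E5B9)
_MIX2 = U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0
ELECTRON_MASS_KEV = 510.99895


@njit(inline="always")
def _splitmix(state):
    state = state + _GOLDEN
    z = state
    z = (z ^ (z >> U64(30))) * _MIX1
    z = (z ^ (z >> U64(27))) * _MIX2
    z = z ^ (z >> U64(31))
    return state, z


@njit(inline="always")
def _uniform(state):
    state, z = _splitmix(state)
    return state, (z >> U64(11)) * _INV53


@njit(inline="always")
def _history_state(seed, batch, hist):
    s = U64(seed) * _GOLDEN ^ U64(batch) * _MIX1 ^ U64(hist) * _MIX2
    s, _ = _splitmix(s)
    s, _ = _splitmix(s)
    return s


@njit(inline="always")
def _interp_row(row, ln_e0, inv_dln, e):
    t = (np.log(e) - ln_e0) * inv_dln
    ne = row.shape[0]
    if t <= 0.0:
        return row[0]
    if t >= ne - 1:
        return row[ne - 1]
    i = int(t)
    f = t - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(inline="always")
def _cdf_pick(cdf, u):
    lo = 0
    hi = cdf.shape[0] - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(inline="always")
def _isotropic(state):
    state, u1 = _uniform(state)
    state, u2 = _uniform(state)
    ct = 2.0 * u1 - 1.0
    st = np.sqrt(max(1.0 - ct * ct, 0.0))
    phi = 2.0 * np.pi * u2
    return state, st * np.cos(phi), st * np.sin(phi), ct


@njit(inline="always")
def _rotate(ux, uy, uz, ct, phi):
    st = np.sqrt(max(1.0 - ct * ct, 0.0))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        den = np.sqrt(1.0 - uz * uz)
        vx = ux * ct + st * (ux * uz * cp - uy * sp) / den
        vy = uy * ct + st * (uy * uz * cp + ux * sp) / den
        vz = uz * ct - st * den * cp
    else:
        vx = st * cp
        vy = st * sp
        vz = ct if uz > 0 else -ct
    norm = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


@njit(inline="always")
def _kahn_compton(state, e_keV):
    """Sample the Compton energy ratio x = E/E' from Klein–Nishina."""
    a = e_keV / ELECTRON_MASS_KEV
    while True:
        state, r1 = _uniform(state)
        state, r2 = _uniform(state)
        state, r3 = _uniform(state)
        if r1 <= (2.0 * a + 1.0) / (2.0 * a + 9.0):
            x = 1.0 + 2.0 * a * r2
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return state, x
        else:
            x = (1.0 + 2.0 * a) / (1.0 + 2.0 * a * r2)
            t = 1.0 - (x - 1.0) / a
            if r3 <= 0.5 * (t * t + 1.0 / x):
                return state, x


@njit(cache=False)
def sample_compton_ratios(e_keV, n, seed):
    """Standalone Kahn sampler (for validation): returns E'/E draws."""
    out = np.empty(n)
    state = _history_state(seed, 0, 1)
    for i in range(n):
        state, x = _kahn_compton(state, e_keV)
        out[i] = 1.0 / x
    return out


@njit(cache=False)
def run_photon_batches(
    mat_idx,
    organ_idx,
    ln_e0,
    inv_dln,
    mu_table,
    pe_table,
    majorant,
    origin,
    h,
    src_voxel,
    src_cdf,
    line_e_keV,
    line_cdf,
    histories,
    batches,
    seed,
    cutoff_keV,
    absorb_all,
    fluence,
    edep,
    fluence_bsq,
    edep_bsq,
    organ_batch,
    conservation,
):
    nx, ny, nz = mat_idx.shape
    inv_vol = 1.0 / (h * h * h)
    per_batch = histories // batches
    for b in range(batches):
        flu_b = np.zeros((nx, ny, nz))
        ede_b = np.zeros((nx, ny, nz))
        org_b = np.zeros(organ_batch.shape[1])
        emitted = 0.0
        deposited = 0.0
        escaped = 0.0
        for hist in range(per_batch):
            state = _history_state(seed, b, hist)
            state, u = _uniform(state)
            si = _cdf_pick(src_cdf, u)
            state, ox = _uniform(state)
            state, oy = _uniform(state)
            state, oz = _uniform(state)
            x = origin[0] + (src_voxel[si, 0] + ox) * h
            y = origin[1] + (src_voxel[si, 1] + oy) * h
            z = origin[2] + (src_voxel[si, 2] + oz) * h
            state, ux, uy, uz = _isotropic(state)
            state, u = _uniform(state)
            e = line_e_keV[_cdf_pick(line_cdf, u)]
            emitted += e
            while True:
                if e < cutoff_keV:
                    ix = int((x - origin[0]) / h)
                    iy = int((y - origin[1]) / h)
                    iz = int((z - origin[2]) / h)
                    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                        ede_b[ix, iy, iz] += e
                        org_b[organ_idx[ix, iy, iz]] += e
                        deposited += e
                    else:
                        escaped += e
                    break
                sig_maj = _interp_row(majorant, ln_e0, inv_dln, e)
                state, u = _uniform(state)
                s = -np.log(u) / sig_maj
                x += s * ux
                y += s * uy
                z += s * uz
                ix = int(np.floor((x - origin[0]) / h))
                iy = int(np.floor((y - origin[1]) / h))
                iz = int(np.floor((z - origin[2]) / h))
                if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                    escaped += e
                    break
                flu_b[ix, iy, iz] += inv_vol / sig_maj
                m = mat_idx[ix, iy, iz]
                mu = _interp_row(mu_table[m], ln_e0, inv_dln, e)
                state, u = _uniform(state)
                if u * sig_maj > mu:
                    continue  # virtual collision
                state, u = _uniform(state)
                if absorb_all or u < _interp_row(pe_table[m], ln_e0, inv_dln, e):
                    ede_b[ix, iy, iz] += e
                    org_b[organ_idx[ix, iy, iz]] += e
                    deposited += e
                    break
                state, ratio = _kahn_compton(state, e)
                e_new = e / ratio
                transfer = e - e_new
                ede_b[ix, iy, iz] += transfer
                org_b[organ_idx[ix, iy, iz]] += transfer
                deposited += transfer
                ct = 1.0 - (ratio - 1.0) * ELECTRON_MASS_KEV / e
                state, u = _uniform(state)
                ux, uy, uz = _rotate(ux, uy, uz, ct, 2.0 * np.pi * u)
                e = e_new
        fluence += flu_b
        edep += ede_b
        fluence_bsq += flu_b * flu_b
        edep_bsq += ede_b * ede_b
        organ_batch[b, :] = org_b
        conservation[b, 0] = emitted
        conservation[b, 1] = deposited
        conservation[b, 2] = escaped


@njit(cache=False)
def run_electron_batches(
    mat_idx,
    organ_idx,
    ln_e0,
    inv_dln,
    stop_table,  # (nmat, ne) MeV/cm
    inv_x0,  # (nmat,) 1/cm
    origin,
    h,
    src_voxel,
    src_cdf,
    spec_e_MeV,
    spec_cdf,
    histories,
    batches,
    seed,
    cutoff_MeV,
    step_fraction,
    edep,
    edep_bsq,
    organ_batch,
    conservation,
):
    nx, ny, nz = mat_idx.shape
    per_batch = histories // batches
    mec2 = ELECTRON_MASS_KEV / 1000.0
    for b in range(batches):
        ede_b = np.zeros((nx, ny, nz))
        org_b = np.zeros(organ_batch.shape[1])
        emitted = 0.0
        deposited = 0.0
        escaped = 0.0
        for hist in range(per_batch):
            state = _history_state(seed, b, hist)
            state, u = _uniform(state)
            si = _cdf_pick(src_cdf, u)
            state, ox = _uniform(state)
            state, oy = _uniform(state)
            state, oz = _uniform(state)
            x = origin[0] + (src_voxel[si, 0] + ox) * h
            y = origin[1] + (src_voxel[si, 1] + oy) * h
            z = origin[2] + (src_voxel[si, 2] + oz) * h
            state, ux, uy, uz = _isotropic(state)
            # inverse-CDF beta energy
            state, u = _uniform(state)
            j = _cdf_pick(spec_cdf, u)
            if j == 0:
                e = spec_e_MeV[0]
            else:
                f = (u - spec_cdf[j - 1]) / max(spec_cdf[j] - spec_cdf[j - 1], 1e-300)
                e = spec_e_MeV[j - 1] + f * (spec_e_MeV[j] - spec_e_MeV[j - 1])
            emitted += e
            while True:
                ix = int(np.floor((x - origin[0]) / h))
                iy = int(np.floor((y - origin[1]) / h))
                iz = int(np.floor((z - origin[2]) / h))
                if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
                    escaped += e
                    break
                if e <= cutoff_MeV:
                    ede_b[ix, iy, iz] += e
                    org_b[organ_idx[ix, iy, iz]] += e
                    deposited += e
                    break
                m = mat_idx[ix, iy, iz]
                sp = _interp_row(stop_table[m], ln_e0, inv_dln, e)
                de = step_fraction * e
                s = de / sp
                if s > 0.5 * h:
                    s = 0.5 * h
                    de = s * sp
                if de >= e:
                    de = e
                ede_b[ix, iy, iz] += de
                org_b[organ_idx[ix, iy, iz]] += de
                deposited += de
                e -= de
                x += s * ux
                y += s * uy
                z += s * uz
                if e <= 0.0:
                    break
                # Highland multiple-scattering deflection over the step
                gamma = 1.0 + e / mec2
                beta2 = 1.0 - 1.0 / (gamma * gamma)
                p_MeV = np.sqrt(max(e * (e + 2.0 * mec2), 1e-30))
                t_rad = s * inv_x0[m]
                if t_rad > 1e-12:
                    corr = 1.0 + 0.038 * np.log(t_rad)
                    if corr < 0.25:
                        corr = 0.25
                    theta0 = 0.0136 / (np.sqrt(beta2) * p_MeV) * np.sqrt(t_rad) * corr
                    state, u1 = _uniform(state)
                    state, u2 = _uniform(state)
                    theta = theta0 * np.sqrt(-2.0 * np.log(max(u1, 1e-300)))
                    if theta > 1.5:
                        theta = 1.5
                    ux, uy, uz = _rotate(ux, uy, uz, np.cos(theta), 2.0 * np.pi * u2)
        edep += ede_b
        edep_bsq += ede_b * ede_b
        organ_batch[b, :] = org_b
        conservation[b, 0] = emitted
        conservation[b, 1] = deposited
        conservation[b, 2] = escaped
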
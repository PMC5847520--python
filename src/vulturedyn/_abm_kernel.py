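"""Numba kernels for the vulture foraging simulation.

The hot loop — 54 ten-minute foraging ticks per day, 365 days, ~50 agents —
runs as nopython-compiled scalar code.  All randomness uses numba's
``np.random`` seeded per replicate, so a (config, seed) pair is bit-for-bit
reproducible.

Geometry: a 200 x 200 km arena of 1 x 1 km patches centred on the origin.
The central circle of area 20,000 km^2 (radius ~79.79 km) is one habitat,
the equal-area exterior the other; an 8-km colony circle and a 50-km
foraging circle are nested inside.  Carcass positions snap to patch centres.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# ---- arena geometry (km) ----
ARENA_HALF = 100.0
R_CENTRAL = math.sqrt(20_000.0 / math.pi)  # 79.788... km
R_COLONY = 8.0
R_FORAGE = 50.0

# stage codes
ADULT, SUBADULT, JUVENILE = 0, 1, 2

MAXC = 2048  # carcass array capacity; daily counts are ~20-40


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's global RNG (for driving tick-level kernels directly)."""
    np.random.seed(seed)


@njit(cache=True)
def is_central(x, y):
    """True when (x, y) lies in the central 20,000 km^2 circle."""
    return x * x + y * y <= R_CENTRAL * R_CENTRAL


@njit(cache=True)
def _snap(v):
    """Snap a coordinate to its 1-km patch centre."""
    return math.floor(v) + 0.5


@njit(cache=True)
def _draw_mass(protected, gamma_shape, gamma_scale, norm_mu, norm_sd):
    """One carcass mass: Gamma in protected habitat, truncated Normal outside."""
    if protected:
        return np.random.gamma(gamma_shape, gamma_scale)
    m = np.random.normal(norm_mu, norm_sd)
    while m <= 0.0:
        m = np.random.normal(norm_mu, norm_sd)
    return m


@njit(cache=True)
def _sample_patch_central():
    """Uniform patch centre inside the central circle."""
    while True:
        r = R_CENTRAL * math.sqrt(np.random.random())
        th = 2.0 * math.pi * np.random.random()
        x = _snap(r * math.cos(th))
        y = _snap(r * math.sin(th))
        if is_central(x, y) and abs(x) < ARENA_HALF and abs(y) < ARENA_HALF:
            return x, y


@njit(cache=True)
def _sample_patch_outer():
    """Uniform patch centre in the exterior habitat."""
    while True:
        x = _snap(np.random.uniform(-ARENA_HALF, ARENA_HALF))
        y = _snap(np.random.uniform(-ARENA_HALF, ARENA_HALF))
        if not is_central(x, y):
            return x, y


@njit(cache=True)
def spawn_carcasses(
    day,
    cx, cy, cmass, cpois, clarge, cage, cactive, n_c,
    central_protected,
    cap_central, cap_outer,
    p_pois_central, p_pois_outer,
    gamma_shape, gamma_scale, norm_mu, norm_sd,
    large_threshold,
):
    """Dawn carcass update: age, decay, compact, then replenish to the caps.

    Small carcasses persist one day, large (> large_threshold) two.  New
    carcasses are drawn until the standing mass of each habitat reaches its
    cap (the final draw is kept, so a cap may be slightly exceeded), placed
    uniformly over the habitat's patches and poisoned independently with the
    habitat's per-carcass probability.  Returns the new carcass count.
    """
    # age & decay, compacting the arrays
    k = 0
    for j in range(n_c):
        if not cactive[j]:
            continue
        age = cage[j] + 1
        lifetime = 2 if clarge[j] else 1
        if age >= lifetime:
            continue
        cx[k] = cx[j]; cy[k] = cy[j]; cmass[k] = cmass[j]
        cpois[k] = cpois[j]; clarge[k] = clarge[j]; cage[k] = age
        cactive[k] = True
        k += 1
    n_c = k

    # standing mass per area
    standing_central = 0.0
    standing_outer = 0.0
    for j in range(n_c):
        if is_central(cx[j], cy[j]):
            standing_central += cmass[j]
        else:
            standing_outer += cmass[j]

    for area in range(2):
        central = area == 0
        cap = cap_central if central else cap_outer
        standing = standing_central if central else standing_outer
        protected = central_protected if central else (not central_protected)
        p_pois = p_pois_central if central else p_pois_outer
        while standing < cap and n_c < MAXC:
            m = _draw_mass(protected, gamma_shape, gamma_scale, norm_mu, norm_sd)
            if central:
                x, y = _sample_patch_central()
            else:
                x, y = _sample_patch_outer()
            cx[n_c] = x; cy[n_c] = y; cmass[n_c] = m
            cpois[n_c] = np.random.random() < p_pois
            clarge[n_c] = m > large_threshold
            cage[n_c] = 0
            cactive[n_c] = True
            standing += m
            n_c += 1
    return n_c


@njit(cache=True)
def nearest_visible(
    x, y, cx, cy, clarge, cactive, coccupied, n_c, vision, vision_enhanced
):
    """Index of the nearest visible carcass, or -1.

    Detection is Euclidean within ``vision`` km, extended to
    ``vision_enhanced`` when the carcass is occupied by a feeding bird
    (local enhancement) or is large.
    """
    best = -1
    best_d2 = 1e30
    for j in range(n_c):
        if not cactive[j]:
            continue
        dx = cx[j] - x
        dy = cy[j] - y
        d2 = dx * dx + dy * dy
        vis = vision_enhanced if (coccupied[j] > 0 or clarge[j]) else vision
        if d2 <= vis * vis and d2 < best_d2:
            best_d2 = d2
            best = j
    return best


@njit(cache=True)
def forage_tick(
    ax, ay, heading, stage, alive, feeding, fed_today,
    memx, memy, has_mem, mem_large,
    cx, cy, cpois, clarge, cactive, coccupied, n_c,
    adults_free, step_km, turn_rad, vision, vision_enhanced,
    n_feedings, n_deaths,
):
    """Advance every live, non-feeding agent one 10-minute tick.

    Priority: nearest visible carcass > remembered patch > correlated random
    walk (±15° turn).  Landing on a poisoned carcass kills instantly — and
    the corpse stays on the carcass, so it keeps (or starts) drawing birds
    from the enhanced 7-km radius: the sentinel-poisoning cascade.
    Otherwise the bird feeds until the forage window closes and remembers
    the patch.  Pre-release adults bounce off the 50-km foraging boundary;
    everyone bounces off the arena edge.
    """
    n = ax.shape[0]
    for i in range(n):
        if not alive[i] or feeding[i]:
            continue
        target = nearest_visible(
            ax[i], ay[i], cx, cy, clarge, cactive, coccupied, n_c,
            vision, vision_enhanced,
        )
        if target >= 0:
            dx = cx[target] - ax[i]
            dy = cy[target] - ay[i]
            d = math.sqrt(dx * dx + dy * dy)
            if d <= step_km:
                ax[i] = cx[target]
                ay[i] = cy[target]
                if cpois[target]:
                    alive[i] = False
                    n_deaths[stage[i]] += 1
                    coccupied[target] += 1  # the corpse stays on the carcass
                else:
                    feeding[i] = True
                    fed_today[i] = True
                    coccupied[target] += 1
                    memx[i] = cx[target]
                    memy[i] = cy[target]
                    has_mem[i] = True
                    mem_large[i] = clarge[target]
                    n_feedings[stage[i]] += 1
                continue
            heading[i] = math.atan2(dy, dx)
        elif has_mem[i]:
            dx = memx[i] - ax[i]
            dy = memy[i] - ay[i]
            d = math.sqrt(dx * dx + dy * dy)
            if d <= step_km:
                ax[i] = memx[i]
                ay[i] = memy[i]
                has_mem[i] = False  # nothing here any more, resume searching
                continue
            heading[i] = math.atan2(dy, dx)
        else:
            if np.random.random() < 0.5:
                heading[i] += turn_rad
            else:
                heading[i] -= turn_rad
        nx = ax[i] + step_km * math.cos(heading[i])
        ny = ay[i] + step_km * math.sin(heading[i])
        if stage[i] == ADULT and not adults_free and nx * nx + ny * ny > R_FORAGE * R_FORAGE:
            heading[i] += math.pi  # bounce off the foraging-range boundary
        elif abs(nx) > ARENA_HALF or abs(ny) > ARENA_HALF:
            heading[i] += math.pi  # bounce off the arena edge
        else:
            ax[i] = nx
            ay[i] = ny


@njit(cache=True)
def _nearest_roost(x, y, roost_x, roost_y):
    best = 0
    best_d2 = 1e30
    for r in range(roost_x.shape[0]):
        dx = roost_x[r] - x
        dy = roost_y[r] - y
        d2 = dx * dx + dy * dy
        if d2 < best_d2:
            best_d2 = d2
            best = r
    return best


@njit(cache=True)
def run_year(
    seed,
    focus_kruger,
    p_pois_protected, p_pois_nonprotected,
    n_roosts,
    n_adults, n_subadults, n_juveniles,
    days, forage_ticks,
    step_km, turn_rad, vision, vision_enhanced,
    adult_release_day,
    cap_protected, cap_nonprotected,
    gamma_shape, gamma_scale, norm_mu, norm_sd,
    large_threshold,
):
    """One replicate year.  Returns (initial, alive, deaths, feedings) per stage.

    focus_kruger=True makes the central circle the protected habitat.
    Adults start in the 8-km colony circle and are confined to the 50-km
    foraging circle until ``adult_release_day``; subadults and juveniles
    start anywhere.  Nights: adults home to the colony (later: nearest
    roost), juveniles to the nearest roost, subadults 50:50 colony/roost.
    """
    np.random.seed(seed)
    n = n_adults + n_subadults + n_juveniles

    stage = np.empty(n, dtype=np.int64)
    ax = np.empty(n)
    ay = np.empty(n)
    home_x = np.empty(n)
    home_y = np.empty(n)
    for i in range(n):
        if i < n_adults:
            stage[i] = ADULT
            r = R_COLONY * math.sqrt(np.random.random())
            th = 2.0 * math.pi * np.random.random()
            ax[i] = r * math.cos(th)
            ay[i] = r * math.sin(th)
            home_x[i] = ax[i]
            home_y[i] = ay[i]
        else:
            stage[i] = SUBADULT if i < n_adults + n_subadults else JUVENILE
            ax[i] = np.random.uniform(-ARENA_HALF, ARENA_HALF)
            ay[i] = np.random.uniform(-ARENA_HALF, ARENA_HALF)
            home_x[i] = ax[i]
            home_y[i] = ay[i]

    roost_x = np.empty(n_roosts)
    roost_y = np.empty(n_roosts)
    for r in range(n_roosts):
        roost_x[r] = _snap(np.random.uniform(-ARENA_HALF, ARENA_HALF))
        roost_y[r] = _snap(np.random.uniform(-ARENA_HALF, ARENA_HALF))

    heading = np.zeros(n)
    alive = np.ones(n, dtype=np.bool_)
    feeding = np.zeros(n, dtype=np.bool_)
    fed_today = np.zeros(n, dtype=np.bool_)
    memx = np.zeros(n)
    memy = np.zeros(n)
    has_mem = np.zeros(n, dtype=np.bool_)
    mem_large = np.zeros(n, dtype=np.bool_)

    cx = np.zeros(MAXC)
    cy = np.zeros(MAXC)
    cmass = np.zeros(MAXC)
    cpois = np.zeros(MAXC, dtype=np.bool_)
    clarge = np.zeros(MAXC, dtype=np.bool_)
    cage = np.zeros(MAXC, dtype=np.int64)
    cactive = np.zeros(MAXC, dtype=np.bool_)
    coccupied = np.zeros(MAXC, dtype=np.int64)
    n_c = 0

    cap_central = cap_protected if focus_kruger else cap_nonprotected
    cap_outer = cap_nonprotected if focus_kruger else cap_protected
    p_pois_central = p_pois_protected if focus_kruger else p_pois_nonprotected
    p_pois_outer = p_pois_nonprotected if focus_kruger else p_pois_protected

    initial = np.zeros(3, dtype=np.int64)
    for i in range(n):
        initial[stage[i]] += 1
    n_deaths = np.zeros(3, dtype=np.int64)
    n_feedings = np.zeros(3, dtype=np.int64)

    for day in range(1, days + 1):
        n_c = spawn_carcasses(
            day, cx, cy, cmass, cpois, clarge, cage, cactive, n_c,
            focus_kruger, cap_central, cap_outer,
            p_pois_central, p_pois_outer,
            gamma_shape, gamma_scale, norm_mu, norm_sd, large_threshold,
        )
        for j in range(MAXC):
            coccupied[j] = 0
        adults_free = day >= adult_release_day
        for i in range(n):
            feeding[i] = False
            fed_today[i] = False
            heading[i] = 2.0 * math.pi * np.random.random()

        for _ in range(forage_ticks):
            forage_tick(
                ax, ay, heading, stage, alive, feeding, fed_today,
                memx, memy, has_mem, mem_large,
                cx, cy, cpois, clarge, cactive, coccupied, n_c,
                adults_free, step_km, turn_rad, vision, vision_enhanced,
                n_feedings, n_deaths,
            )

        # dusk: memory survives the night only toward food that will still
        # be there (a large carcass persisting into its second day); everyone
        # homes (the 2-hour homing window at 48 km/h is modelled as arrival)
        for i in range(n):
            if not alive[i]:
                continue
            if not fed_today[i] or not mem_large[i]:
                has_mem[i] = False
            if stage[i] == ADULT:
                if day < adult_release_day:
                    ax[i] = home_x[i]
                    ay[i] = home_y[i]
                else:
                    r = _nearest_roost(ax[i], ay[i], roost_x, roost_y)
                    ax[i] = roost_x[r]
                    ay[i] = roost_y[r]
            elif stage[i] == JUVENILE:
                r = _nearest_roost(ax[i], ay[i], roost_x, roost_y)
                ax[i] = roost_x[r]
                ay[i] = roost_y[r]
            else:  # subadult: prospecting coin flip
                if np.random.random() < 0.5:
                    ax[i] = 0.0
                    ay[i] = 0.0
                else:
                    r = _nearest_roost(ax[i], ay[i], roost_x, roost_y)
                    ax[i] = roost_x[r]
                    ay[i] = roost_y[r]

    alive_counts = np.zeros(3, dtype=np.int64)
    for i in range(n):
        if alive[i]:
            alive_counts[stage[i]] += 1
    return initial, alive_counts, n_deaths, n_feedings
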
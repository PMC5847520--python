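"""Agent-based foraging model: geometry, carcasses, movement, full runs."""

import math

import numpy as np
import pytest

import vulturedyn._abm_kernel as K
from vulturedyn import abm_core


@pytest.fixture(scope="module")
def default_config():
    return abm_core.ABMConfig()


def make_carcasses(entries):
    """Build kernel carcass arrays from (x, y, mass, poisoned) tuples."""
    n = len(entries)
    cx = np.zeros(K.MAXC)
    cy = np.zeros(K.MAXC)
    cpois = np.zeros(K.MAXC, dtype=np.bool_)
    clarge = np.zeros(K.MAXC, dtype=np.bool_)
    cactive = np.zeros(K.MAXC, dtype=np.bool_)
    coccupied = np.zeros(K.MAXC, dtype=np.int64)
    for j, (x, y, mass, pois) in enumerate(entries):
        cx[j], cy[j] = x, y
        cpois[j] = pois
        clarge[j] = mass > 1000
        cactive[j] = True
    return cx, cy, cpois, clarge, cactive, coccupied, n


def make_agents(positions, stage=K.ADULT):
    n = len(positions)
    ax = np.array([p[0] for p in positions], dtype=float)
    ay = np.array([p[1] for p in positions], dtype=float)
    return dict(
        ax=ax, ay=ay, heading=np.zeros(n),
        stage=np.full(n, stage, dtype=np.int64),
        alive=np.ones(n, dtype=np.bool_),
        feeding=np.zeros(n, dtype=np.bool_),
        fed_today=np.zeros(n, dtype=np.bool_),
        memx=np.zeros(n), memy=np.zeros(n),
        has_mem=np.zeros(n, dtype=np.bool_),
        mem_large=np.zeros(n, dtype=np.bool_),
    )


def tick(agents, carcasses, adults_free=True, cfg=None):
    cfg = cfg or abm_core.ABMConfig()
    cx, cy, cpois, clarge, cactive, coccupied, n_c = carcasses
    feeds = np.zeros(3, dtype=np.int64)
    deaths = np.zeros(3, dtype=np.int64)
    K.forage_tick(
        agents["ax"], agents["ay"], agents["heading"], agents["stage"],
        agents["alive"], agents["feeding"], agents["fed_today"],
        agents["memx"], agents["memy"], agents["has_mem"], agents["mem_large"],
        cx, cy, cpois, clarge, cactive, coccupied, n_c,
        adults_free, cfg.step_km, math.radians(cfg.turn_deg),
        cfg.vision_km, cfg.vision_enhanced_km, feeds, deaths,
    )
    return feeds, deaths


class TestConfig:
    def test_derived_quantities(self, default_config):
        assert default_config.step_km == pytest.approx(4.0)
        assert default_config.forage_ticks == 54
        assert default_config.carrion_cap_protected == pytest.approx(3000.0)
        assert default_config.carrion_cap_nonprotected == pytest.approx(6000.0)
        assert default_config.poison_probability("protected") == pytest.approx(1 / 1000)
        assert default_config.poison_probability("nonprotected") == pytest.approx(1 / 100)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"focus": "Swaziland"},
            {"poison_rate_protected": 0},
            {"n_roosts": 0},
            {"n_adults": -1},
            {"day_length_s": 1000},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            abm_core.ABMConfig(**kwargs)


class TestWorld:
    def test_habitat_areas_are_equal_up_to_quantization(self, default_config):
        w = abm_core.init_world(default_config)
        protected = w.count_patches("protected")
        nonprotected = w.count_patches("nonprotected")
        assert protected + nonprotected == 40_000
        assert abs(protected - 20_000) < 50  # patch quantization of the circle

    def test_focus_flip_swaps_labels_patchwise(self, rng):
        for _ in range(200):
            x, y = rng.uniform(-100, 100, 2)
            a = abm_core.habitat_at(x, y, "Kruger")
            b = abm_core.habitat_at(x, y, "KZN")
            assert {a, b} == {"protected", "nonprotected"}

    def test_initial_agent_placement(self, default_config):
        w = abm_core.init_world(default_config, seed=3)
        assert len(w.adult_xy) == 26
        assert len(w.subadult_xy) == 13
        assert len(w.juvenile_xy) == 13
        r = np.hypot(w.adult_xy[:, 0], w.adult_xy[:, 1])
        assert np.all(r <= K.R_COLONY + 1e-9)
        assert np.all(np.abs(w.roost_xy) <= 100)


class TestCarcassMass:
    def test_gamma_moments_confirm_rate_parameterization(self, rng):
        cfg = abm_core.ABMConfig()
        draws = np.array(
            [abm_core.draw_carcass_mass("protected", rng, cfg) for _ in range(100_000)]
        )
        # mean = shape/rate = 300 kg; a scale parameterization would give 0.0048
        assert abs(draws.mean() - 300.0) < 3.0
        tail = (draws > 1000).mean()
        se = math.sqrt(0.02745 * (1 - 0.02745) / draws.size)
        assert abs(tail - 0.02745) < 4 * se

    def test_normal_moments_and_truncation(self, rng):
        cfg = abm_core.ABMConfig()
        draws = np.array(
            [abm_core.draw_carcass_mass("nonprotected", rng, cfg) for _ in range(100_000)]
        )
        assert abs(draws.mean() - 500.0) < 1.0
        assert draws.min() > 0


class TestSpawning:
    def _spawn(self, focus_kruger, p_central=0.0, p_outer=0.0, seed=123):
        K.seed_rng(seed)
        cx = np.zeros(K.MAXC); cy = np.zeros(K.MAXC); cmass = np.zeros(K.MAXC)
        cpois = np.zeros(K.MAXC, dtype=np.bool_)
        clarge = np.zeros(K.MAXC, dtype=np.bool_)
        cage = np.zeros(K.MAXC, dtype=np.int64)
        cactive = np.zeros(K.MAXC, dtype=np.bool_)
        n_c = K.spawn_carcasses(
            1, cx, cy, cmass, cpois, clarge, cage, cactive, 0,
            focus_kruger, 3000.0, 6000.0, p_central, p_outer,
            1.2, 250.0, 500.0, 100.0, 1000.0,
        )
        return cx, cy, cmass, cpois, clarge, cactive, n_c

    def test_caps_reached_but_not_doubled(self):
        cx, cy, cmass, _, _, _, n_c = self._spawn(True)
        central = np.array([K.is_central(cx[j], cy[j]) for j in range(n_c)])
        m_central = cmass[:n_c][central].sum()
        m_outer = cmass[:n_c][~central].sum()
        assert 3000 <= m_central  # cap reached
        assert m_central - 3000 < cmass[:n_c][central].max()  # overshoot < last draw
        assert 6000 <= m_outer
        assert m_outer - 6000 < cmass[:n_c][~central].max()

    def test_degenerate_poison_rate_poisons_everything(self):
        _, _, _, cpois, _, _, n_c = self._spawn(True, p_central=1.0, p_outer=1.0)
        assert n_c > 0
        assert cpois[:n_c].all()

    def test_large_flag_thresholds(self):
        cx, cy, cmass, _, clarge, _, n_c = self._spawn(False, seed=7)
        assert np.array_equal(clarge[:n_c], cmass[:n_c] > 1000)


def nv(carc, x=0.0, y=0.0):
    cx, cy, _cpois, clarge, cactive, coccupied, n_c = carc
    return K.nearest_visible(x, y, cx, cy, clarge, cactive, coccupied, n_c, 6.0, 7.0)


class TestDetection:
    def test_vision_threshold_semantics(self):
        assert nv(make_carcasses([(5.0, 0.0, 500, False)])) == 0
        assert nv(make_carcasses([(6.5, 0.0, 500, False)])) == -1

    def test_local_enhancement_extends_vision(self):
        carc = make_carcasses([(6.5, 0.0, 500, False)])
        carc[5][0] = 1  # one bird already feeding
        assert nv(carc) == 0

    def test_large_carcass_always_enhanced(self):
        assert nv(make_carcasses([(6.5, 0.0, 1500, False)])) == 0

    def test_nearest_wins(self):
        assert nv(make_carcasses([(5.0, 0.0, 500, False), (3.0, 0.0, 500, False)])) == 1


class TestMovement:
    def test_moves_toward_visible_carcass_and_lands(self):
        agents = make_agents([(0.0, 0.0)])
        carc = make_carcasses([(5.5, 0.0, 500, False)])
        tick(agents, carc)
        assert agents["ax"][0] == pytest.approx(4.0)  # one 4-km step closer
        feeds, _ = tick(agents, carc)
        assert agents["feeding"][0]
        assert agents["has_mem"][0]
        assert feeds[K.ADULT] == 1
        assert carc[5][0] == 1  # occupied

    def test_poisoned_carcass_kills_and_leaves_corpse_enhancement(self):
        agents = make_agents([(3.0, 0.0)])
        carc = make_carcasses([(0.0, 0.0, 500, True)])
        _, deaths = tick(agents, carc)
        assert not agents["alive"][0]
        assert deaths[K.ADULT] == 1
        assert carc[5][0] == 1  # corpse counts toward local enhancement

    def test_dead_agents_never_move(self):
        agents = make_agents([(10.0, 10.0)])
        agents["alive"][0] = False
        carc = make_carcasses([])
        tick(agents, carc)
        assert agents["ax"][0] == 10.0 and agents["ay"][0] == 10.0

    def test_memory_guides_then_clears_on_empty_patch(self):
        agents = make_agents([(0.0, 0.0)])
        agents["has_mem"][0] = True
        agents["memx"][0], agents["memy"][0] = 10.5, 0.0
        carc = make_carcasses([])
        tick(agents, carc)
        assert agents["ax"][0] == pytest.approx(4.0)
        tick(agents, carc)
        tick(agents, carc)
        assert agents["ax"][0] == pytest.approx(10.5)
        assert not agents["has_mem"][0]

    def test_confined_adult_bounces_at_foraging_radius(self):
        agents = make_agents([(49.0, 0.0)])
        agents["heading"][0] = 0.0
        carc = make_carcasses([])
        K.seed_rng(1)
        for _ in range(30):
            tick(agents, carc, adults_free=False)
            assert math.hypot(agents["ax"][0], agents["ay"][0]) <= K.R_FORAGE + 1e-9

    def test_random_walk_displacement_matches_crw_oracle(self):
        """Mean squared displacement of the ±15° correlated walk follows the
        closed-form CRW formula E[R^2] = n l^2 + 2 l^2 c/(1-c) (n - (1-c^n)/(1-c))."""
        n_steps, l, reps = 20, 4.0, 600
        c = math.cos(math.radians(15.0))
        msd_theory = (
            n_steps * l**2
            + 2 * l**2 * (c / (1 - c)) * (n_steps - (1 - c**n_steps) / (1 - c))
        )
        K.seed_rng(2024)
        carc = make_carcasses([])
        sq = []
        for _ in range(reps):
            agents = make_agents([(0.0, 0.0)])
            for _ in range(n_steps):
                tick(agents, carc)
            sq.append(agents["ax"][0] ** 2 + agents["ay"][0] ** 2)
        msd = float(np.mean(sq))
        se = float(np.std(sq, ddof=1) / math.sqrt(reps))
        assert abs(msd - msd_theory) < 4 * se
        # hard upper bound: cannot outrun straight flight
        assert max(sq) <= (n_steps * l) ** 2 + 1e-9


class TestFullRuns:
    def test_no_poisoning_means_no_mortality(self):
        cfg = abm_core.with_poisoning_disabled(abm_core.ABMConfig(seed=5))
        res = abm_core.run_year(cfg)
        assert res.survival_pct == {"adult": 100.0, "subadult": 100.0, "juvenile": 100.0}
        assert sum(res.deaths.values()) == 0

    def test_bitwise_determinism(self):
        cfg = abm_core.ABMConfig(seed=31)
        a, b = abm_core.run_year(cfg), abm_core.run_year(cfg)
        assert a.alive == b.alive
        assert a.deaths == b.deaths
        assert a.feedings == b.feedings

    def test_agent_conservation(self):
        res = abm_core.run_year(abm_core.ABMConfig(focus="KZN", seed=8))
        for s in abm_core.STAGES:
            assert res.alive[s] + res.deaths[s] == res.initial[s]
        assert res.initial == {"adult": 26, "subadult": 13, "juvenile": 13}

    def test_protective_effect_of_low_poisoning_focus(self):
        """With protected poisoning 10x rarer, adults survive far better when
        the colony sits inside the protected area."""
        k = abm_core.run_experiment(abm_core.ABMConfig(focus="Kruger", seed=21), replicates=8)
        z = abm_core.run_experiment(abm_core.ABMConfig(focus="KZN", seed=21), replicates=8)
        mean = lambda t, s: t.summary.set_index("stage").loc[s, "mean_survival"]
        assert mean(k, "adult") > mean(z, "adult")

    def test_experiment_replicates_are_stable_under_extension(self):
        cfg = abm_core.ABMConfig(seed=13)
        short = abm_core.run_experiment(cfg, replicates=3)
        longer = abm_core.run_experiment(cfg, replicates=5)
        a = short.replicates.sort_values(["replicate", "stage"]).reset_index(drop=True)
        b = (
            longer.replicates[longer.replicates["replicate"] < 3]
            .sort_values(["replicate", "stage"])
            .reset_index(drop=True)
        )
        assert a.equals(b)

    def test_experiment_validation(self):
        with pytest.raises(ValueError):
            abm_core.run_experiment(abm_core.ABMConfig(), replicates=0)
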
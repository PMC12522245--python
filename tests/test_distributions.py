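"""Correctness of the four-parameter distribution families.

Each family is checked against independent numerical oracles: adaptive
quadrature for the density normalization, bracketed inversion for the
CDF/quantile pair, the closed-form normal density at the sinh-arcsinh
families' normality point, and Kolmogorov-Smirnov agreement between exact
samples and the CDF.
"""

import math
import zlib

import numpy as np
import pytest
from scipy import integrate, stats

from pasenorm import distributions as dist
from pasenorm.distributions import FAMILY_NAMES, ParamError, ParamVector

# hand-picked in-domain skewed parameter points per family (mu, sigma, nu, tau)
SKEWED = {
    "SHASH": (0.5, 1.2, 0.7, 1.4),
    "SHASHo": (-1.0, 0.8, -0.4, 1.2),
    "SHASHo2": (1.0, 2.0, -0.3, 1.1),
    "SEP1": (0.0, 1.5, 1.2, 1.7),
    "SEP2": (2.0, 1.0, -1.0, 2.5),
    "SEP4": (0.0, 1.0, 1.7, 2.3),
    "JSU": (0.0, 1.0, 0.7, 1.6),
    "JSUo": (3.0, 2.0, -0.5, 1.4),
    "ST1": (0.0, 1.0, 2.0, 5.0),
    "ST5": (1.0, 0.5, 0.8, 0.5),
}


def random_params(name, rng):
    """A random in-domain, moderately-shaped parameter point."""
    fam = dist.get_family(name)
    mu = rng.uniform(-2, 2)
    sigma = rng.uniform(0.5, 2.0)
    if fam.nu_domain == "positive":
        nu = rng.uniform(0.7, 2.5)
    else:
        nu = rng.uniform(-1.5, 1.5)
    lo, hi = {"ST1": (3.0, 12.0), "ST5": (0.2, 0.8)}.get(name, (0.8, 2.5))
    tau = rng.uniform(lo, hi)
    return ParamVector(mu, sigma, nu, tau)


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_density_integrates_to_one(name):
    rng = np.random.default_rng(zlib.crc32(name.encode()))
    fam = dist.get_family(name)
    for pv in [ParamVector(*SKEWED[name]), random_params(name, rng)]:
        total, _ = integrate.quad(lambda x: dist.pdf(fam, x, pv),
                                  -np.inf, np.inf, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_quantile_inverts_cdf(name):
    rng = np.random.default_rng(1 + zlib.crc32(name.encode()))
    fam = dist.get_family(name)
    for pv in [ParamVector(*SKEWED[name]), random_params(name, rng)]:
        for level in (0.05, 0.3, 0.6, 0.95):
            x = dist.quantile(fam, level, pv)
            p = dist.cdf(fam, x, pv)
            assert 0 < p < 1
            assert dist.quantile(fam, p, pv) == pytest.approx(x, abs=1e-8)


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_symmetry_point_centres_on_mu(name):
    """At each family's symmetric setting the location parameter is the
    median: cdf(mu) = 1/2 and quantile(1/2) = mu."""
    fam = dist.get_family(name)
    pv = fam.symmetric_example._replace(mu=3.7, sigma=1.9)
    assert dist.cdf(fam, pv.mu, pv) == pytest.approx(0.5, abs=1e-9)
    assert dist.quantile(fam, 0.5, pv) == pytest.approx(pv.mu, abs=1e-7)


@pytest.mark.parametrize("name", ["SHASH", "SHASHo", "SHASHo2"])
def test_sinh_arcsinh_normal_limit(name):
    """The sinh-arcsinh families collapse to N(mu, sigma^2) exactly at
    their normality settings."""
    fam = dist.get_family(name)
    ref = fam.normal_reference._replace(mu=1.0, sigma=2.0)
    xs = np.linspace(-6, 8, 41)
    got = dist.pdf(fam, xs, ref)
    want = stats.norm.pdf(xs, 1.0, 2.0)
    np.testing.assert_allclose(got, want, atol=1e-10)
    np.testing.assert_allclose(dist.cdf(fam, xs, ref),
                               stats.norm.cdf(xs, 1.0, 2.0), atol=1e-10)


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_cdf_monotone_and_proper(name):
    fam = dist.get_family(name)
    pv = ParamVector(*SKEWED[name])
    xs = pv.mu + pv.sigma * np.linspace(-8, 8, 161)
    cs = np.asarray(dist.cdf(fam, xs, pv))
    assert np.all(np.diff(cs) >= -1e-12)
    assert np.all((cs >= 0) & (cs <= 1))
    # heavy-tailed settings (e.g. skew-t with few df) still hold most mass here
    assert cs[0] < 0.01 and cs[-1] > 0.8


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_samples_match_cdf_ks(name):
    pv = ParamVector(*SKEWED[name])
    fam = dist.get_family(name)
    s = dist.sample(fam, 100_000, pv, seed=42)
    res = stats.kstest(s, lambda v: np.asarray(dist.cdf(fam, v, pv)))
    assert res.pvalue > 0.01


@pytest.mark.parametrize("name", FAMILY_NAMES)
def test_unimodal_with_mode_at_mu_when_symmetric(name):
    fam = dist.get_family(name)
    pv = fam.symmetric_example
    xs = np.linspace(pv.mu - 4 * pv.sigma, pv.mu + 4 * pv.sigma, 401)
    d = np.asarray(dist.pdf(fam, xs, pv))
    peak = xs[np.argmax(d)]
    assert abs(peak - pv.mu) < 0.05
    rising = np.diff(d[: len(d) // 2])
    falling = np.diff(d[len(d) // 2:])
    assert np.all(rising >= -1e-12) and np.all(falling <= 1e-12)


class TestDomainChecks:
    def test_sigma_must_be_positive(self):
        with pytest.raises(ParamError, match="sigma"):
            dist.pdf("SHASHo2", 0.0, ParamVector(0, -1.0, 0, 1))

    def test_tau_must_be_positive(self):
        with pytest.raises(ParamError, match="tau"):
            dist.cdf("JSU", 0.0, ParamVector(0, 1.0, 0, 0.0))

    @pytest.mark.parametrize("name", ["SHASH", "SEP4"])
    def test_positive_nu_families_reject_nonpositive_nu(self, name):
        with pytest.raises(ParamError, match="nu"):
            dist.quantile(name, 0.5, ParamVector(0, 1.0, -0.5, 1.0))

    def test_interior_p_required(self):
        with pytest.raises(ValueError):
            dist.quantile("JSUo", 1.0, ParamVector(0, 1, 0, 1))

    def test_unknown_family(self):
        with pytest.raises(KeyError, match="BCT"):
            dist.get_family("BCT")


class TestLoglik:
    def test_single_observation_is_log_density(self):
        pv = ParamVector(0.0, 1.0, 0.0, 1.0)
        res = dist.loglik("SHASHo", [0.3], ParamVector(0.0, 1.0, 0.0, 1.0), [1.0])
        want = float(np.log(dist.pdf("SHASHo", 0.3, pv)))
        assert res.value == pytest.approx(want, rel=1e-12)

    def test_linear_in_weights(self, rng):
        x = rng.normal(size=50)
        pv = ParamVector(0.1, 1.2, 0.2, 1.1)
        w = rng.uniform(0.5, 2.0, size=50)
        l1 = dist.loglik("SHASHo", x, pv, w).value
        l2 = dist.loglik("SHASHo", x, pv, 2 * w).value
        assert l2 == pytest.approx(2 * l1, rel=1e-12)

    def test_gaussian_special_case_closed_form(self, rng):
        x = rng.normal(2.0, 3.0, size=200)
        pv = ParamVector(2.0, 3.0, 0.0, 1.0)  # SHASHo normal limit
        got = dist.loglik("SHASHo", x, pv).value
        want = float(np.sum(stats.norm.logpdf(x, 2.0, 3.0)))
        assert got == pytest.approx(want, rel=1e-10)

    def test_per_observation_parameters(self, rng):
        x = rng.normal(size=30)
        mu = np.linspace(-1, 1, 30)
        pv = ParamVector(mu, 1.0, 0.0, 1.0)
        got = dist.loglik("SHASHo", x, pv).value
        want = float(np.sum(stats.norm.logpdf(x, mu, 1.0)))
        assert got == pytest.approx(want, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dist.loglik("SHASHo", [0.0, 1.0],
                        ParamVector(np.zeros(3), 1.0, 0.0, 1.0))

    def test_underflow_flagged_as_minus_inf(self):
        res = dist.loglik("SHASHo2", [1e200], ParamVector(0, 1, 0, 1))
        assert res.value == -math.inf
        assert res.n_underflow == 1

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            dist.loglik("JSU", [0.0], ParamVector(0, 1, 0, 1), [0.0])


def test_sampling_deterministic_given_seed():
    pv = ParamVector(*SKEWED["SEP2"])
    a = dist.sample("SEP2", 1000, pv, seed=9)
    b = dist.sample("SEP2", 1000, pv, seed=9)
    np.testing.assert_array_equal(a, b)
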
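"""Index unit tests plus an independently coded plain-arithmetic oracle.

The oracle below works straight from (code, percentage) pairs with its own
minimal regex — it never touches the package's descriptor/aggregation path.
"""

import math
import re

import pytest
from hypothesis import given, settings, strategies as st

from lipidqi.errors import UndefinedIndexError
from lipidqi.indices import (
    compute_all,
    h_over_h,
    hpi,
    ia,
    it,
    ps,
    sed,
    tfa,
    ui,
)
from lipidqi.nomenclature import parse_shorthand
from lipidqi.profile import FattyAcidProfile, GroupSums, ProfileEntry, aggregate
from lipidqi.synthetic import ProfileSimSpec, simulate_profile

# ---------------------------------------------------------------------------
# independent oracle

_ORACLE_RE = re.compile(r"^C(\d+):(\d+)(?:n(\d+))?([ct])?$")


def oracle_indices(pairs):
    """Eight index values from raw (code, pct) pairs by direct arithmetic."""
    pct = dict(pairs)

    def db(code):
        return int(_ORACLE_RE.match(code).group(2))

    def omega(code):
        m = _ORACLE_RE.match(code).group(3)
        return int(m) if m else None

    def geom(code):
        return _ORACLE_RE.match(code).group(4)

    sfa = sum(v for c, v in pct.items() if db(c) == 0)
    mufa = sum(v for c, v in pct.items() if db(c) == 1)
    pufa = sum(v for c, v in pct.items() if db(c) >= 2)
    ufa = mufa + pufa
    n3 = sum(v for c, v in pct.items() if db(c) >= 2 and omega(c) == 3)
    n6 = sum(v for c, v in pct.items() if db(c) >= 2 and omega(c) == 6)
    trans = sum(v for c, v in pct.items() if geom(c) == "t")
    oleic = sum(v for c, v in pct.items()
                if c.startswith("C18:1") and geom(c) == "c")
    get = lambda code: pct.get(code, 0.0)

    out = {}
    out["ps"] = pufa / sfa if sfa > 0 else None
    ia_num = get("C12:0") + 4 * get("C14:0") + get("C16:0")
    out["ia"] = ia_num / ufa if ufa > 0 else None
    if n6 > 0:
        it_den = 0.5 * mufa + 0.5 * n6 + 3 * n3 + n3 / n6
        out["it"] = (get("C14:0") + get("C16:0") + get("C18:0")) / it_den if it_den > 0 else None
    else:
        out["it"] = None
    hh_den = get("C12:0") + get("C14:0") + get("C16:0")
    out["h_over_h"] = (oleic + pufa) / hh_den if hh_den > 0 else None
    out["hpi"] = ufa / ia_num if ia_num > 0 else None
    out["ui"] = sum(db(c) * v for c, v in pct.items())
    out["sed"] = get("C20:5n3") + get("C22:6n3")
    out["tfa"] = trans
    return out


# ---------------------------------------------------------------------------
# single-index examples (published two-decimal values and hand arithmetic)

@pytest.fixture(scope="module")
def g_ano(ano):
    return aggregate(ano)


@pytest.fixture(scope="module")
def g_rho(rho):
    return aggregate(rho)


def zeros_with(**kw):
    base = dict(sfa=0.0, mufa=0.0, pufa=0.0, n3=0.0, n6=0.0, tfa=0.0, cis_c18_1=0.0)
    base.update({k: v for k, v in kw.items() if k in base})
    named = {c: 0.0 for c in ("C12:0", "C14:0", "C16:0", "C18:0", "C20:5n3", "C22:6n3")}
    named.update(kw.get("named", {}))
    polyene = {k: 0.0 for k in range(1, 7)}
    polyene.update(kw.get("polyene", {}))
    return GroupSums(named=named, polyene=polyene, **base)


class TestPs:
    def test_ano(self, g_ano):
        assert round(ps(g_ano), 2) == 0.37

    def test_zero_pufa(self):
        assert ps(zeros_with(sfa=40.0)) == 0.0

    def test_hand_arithmetic(self):
        assert ps(zeros_with(pufa=15.54, sfa=41.75)) == pytest.approx(15.54 / 41.75)

    def test_undefined(self):
        with pytest.raises(UndefinedIndexError):
            ps(zeros_with(pufa=10.0))


class TestIa:
    def test_ano(self, g_ano):
        assert round(ia(g_ano), 2) == 0.68

    def test_all_named_zero(self):
        assert ia(zeros_with(mufa=50.0)) == 0.0

    def test_hand_arithmetic(self):
        g = zeros_with(mufa=42.71, pufa=15.54,
                       named={"C14:0": 1.72, "C16:0": 33.02})
        assert ia(g) == pytest.approx((4 * 1.72 + 33.02) / 58.25)

    def test_undefined_when_no_ufa(self):
        with pytest.raises(UndefinedIndexError):
            ia(zeros_with(sfa=100.0))


class TestIt:
    def test_ano(self, g_ano):
        assert round(it(g_ano), 2) == 1.15

    def test_zero_numerator(self):
        assert it(zeros_with(mufa=30.0, n3=2.0, n6=10.0, pufa=12.0)) == 0.0

    def test_rho_hand_arithmetic(self, g_rho):
        expected = 40.47 / (17.765 + 10.125 + 8.43 + 2.81 / 20.25)
        assert it(g_rho) == pytest.approx(expected, abs=1e-9)

    def test_undefined_without_n6(self):
        with pytest.raises(UndefinedIndexError):
            it(zeros_with(mufa=30.0, n3=2.0, pufa=2.0))


class TestHoverH:
    def test_rho(self, g_rho):
        assert round(h_over_h(g_rho), 2) == 0.82

    def test_zero_numerator(self):
        assert h_over_h(zeros_with(named={"C16:0": 30.0})) == 0.0

    def test_ano_hand_arithmetic(self, g_ano):
        assert h_over_h(g_ano) == pytest.approx(19.84 / 34.74, abs=1e-9)

    def test_undefined(self):
        with pytest.raises(UndefinedIndexError):
            h_over_h(zeros_with(pufa=10.0))


class TestHpi:
    def test_ano(self, g_ano):
        assert round(hpi(g_ano), 2) == 1.46

    def test_reciprocal_of_ia(self, g_ano, g_rho):
        for g in (g_ano, g_rho):
            assert hpi(g) * ia(g) == pytest.approx(1.0, abs=1e-12)

    def test_rho_hand_arithmetic(self, g_rho):
        assert hpi(g_rho) == pytest.approx(58.59 / 55.14, abs=1e-9)


class TestUi:
    def test_ano(self, g_ano):
        assert round(ui(g_ano), 2) == 104.01

    def test_saturated_only(self):
        assert ui(zeros_with(sfa=100.0)) == 0.0

    def test_weighted_sum_by_hand(self):
        g = zeros_with(mufa=42.71, pufa=15.54,
                       polyene={1: 42.71, 2: 1.10, 3: 1.89, 4: 10.27, 5: 1.33, 6: 0.95})
        expected = 42.71 + 2.20 + 5.67 + 41.08 + 6.65 + 5.70
        assert ui(g) == pytest.approx(expected, abs=1e-9)


class TestSed:
    def test_ano(self, g_ano):
        assert sed(g_ano) == pytest.approx(2.28)

    def test_absent(self):
        assert sed(zeros_with()) == 0.0

    def test_rho_hand_sum(self, g_rho):
        assert sed(g_rho) == pytest.approx(2.61 + 0.20)


class TestTfa:
    def test_rho(self, g_rho):
        assert tfa(g_rho) == pytest.approx(3.14)

    def test_no_trans(self):
        assert tfa(zeros_with(mufa=10.0)) == 0.0

    def test_ano_single_trans_entry(self, g_ano):
        assert tfa(g_ano) == pytest.approx(2.26)


PUBLISHED = {
    "Ano": {"ps": 0.37, "ia": 0.68, "it": 1.15, "h_over_h": 0.57,
            "hpi": 1.46, "ui": 104.01, "sed": 2.28, "tfa": 2.26},
    "Rho": {"ps": 0.56, "ia": 0.94, "it": 1.11, "h_over_h": 0.82,
            "hpi": 1.06, "ui": 102.72, "sed": 2.81, "tfa": 3.14},
}


class TestComputeAll:
    def test_reference_columns(self, ano, rho):
        for p in (ano, rho):
            report = compute_all(p)
            assert report.undefined == ()
            assert report.rounded(2) == PUBLISHED[p.sample_id]

    def test_empty_profile_flags_ratios(self):
        report = compute_all(FattyAcidProfile("empty", ()))
        assert set(report.undefined) == {"ps", "ia", "it", "h_over_h", "hpi"}
        assert report.ui == report.sed == report.tfa == 0.0


# ---------------------------------------------------------------------------
# properties

def scaled(profile, c):
    return FattyAcidProfile(
        profile.sample_id,
        tuple(ProfileEntry(e.descriptor, e.percentage * c, nd=e.nd) for e in profile),
    )


@pytest.mark.parametrize("c", [0.5, 2.0, 3.7])
def test_scale_invariance(ano, c):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b = compute_all(ano), compute_all(scaled(ano, c))
    for name in ("ps", "ia", "h_over_h", "hpi"):
        assert getattr(b, name) == pytest.approx(getattr(a, name), rel=1e-12)
    for name in ("ui", "sed", "tfa"):
        assert getattr(b, name) == pytest.approx(c * getattr(a, name), rel=1e-12)


def test_it_is_not_scale_invariant(ano):
    # the thrombogenicity denominator mixes scale-covariant class sums with
    # the dimensionless n3/n6 ratio, so the index drifts up as the
    # composition is scaled (and only approaches invariance asymptotically)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        small = compute_all(scaled(ano, 0.5)).it
        base = compute_all(ano).it
        big = compute_all(scaled(ano, 2.0)).it
    assert small < base < big
    limit = base * (0.5 * 42.71 + 0.5 * 13.26 + 3 * 2.28 + 2.28 / 13.26) / (
        0.5 * 42.71 + 0.5 * 13.26 + 3 * 2.28)
    assert big < limit


def bump(profile, code, delta):
    entries = tuple(
        ProfileEntry(e.descriptor, e.percentage + (delta if e.descriptor.code == code else 0.0))
        for e in profile
    )
    return FattyAcidProfile(profile.sample_id, entries)


@pytest.mark.parametrize("code", ["C20:5n3", "C22:6n3"])
def test_n3_monotonicity(ano, code):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base, more = compute_all(ano), compute_all(bump(ano, code, 5.0))
    assert more.it < base.it
    assert more.ps > base.ps
    assert more.ui > base.ui
    assert more.sed > base.sed


def test_oracle_equivalence_200_random_profiles():
    for seed in range(200):
        profile = simulate_profile(ProfileSimSpec(seed=seed, nd_probability=0.2),
                                   sample_id=f"sim{seed}")
        report = compute_all(profile)
        expected = oracle_indices(
            [(e.descriptor.code, e.percentage) for e in profile]
        )
        for name, want in expected.items():
            got = getattr(report, name)
            if want is None:
                assert got is None, name
            else:
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12), name


@given(st.floats(min_value=0.01, max_value=60), st.floats(min_value=0.01, max_value=60),
       st.floats(min_value=0.01, max_value=60))
def test_ia_hpi_reciprocity_property(c14, c16, mufa):
    g = zeros_with(mufa=mufa, named={"C14:0": c14, "C16:0": c16})
    assert ia(g) * hpi(g) == pytest.approx(1.0, abs=1e-12)
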
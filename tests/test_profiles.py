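import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genaccount import InvalidInputError
from genaccount.profiles import (
    AgeProfile,
    TaxProfileSet,
    TransferProfileSet,
    expand_group_profile,
    per_capita_profile,
    sum_taxes,
    sum_transfers,
    weight_by_participation,
)

N = 78


def make_transfer_set(n=N, **overrides):
    kw = {}
    for name in ("education", "healthcare", "wages", "pensions", "unemp"):
        kw[f"{name}_amount"] = AgeProfile.zeros(n)
        if name not in ("healthcare", "pensions"):
            kw[f"{name}_part"] = AgeProfile.zeros(n)
    kw.update(overrides)
    return TransferProfileSet(**kw)


def make_tax_set(n=N, **overrides):
    kw = {name: AgeProfile.zeros(n) for name in (
        "ss", "income", "corporate", "nonresident", "alcohol",
        "tobacco", "fuel", "vat", "other")}
    kw.update(overrides)
    return TaxProfileSet(**kw)


class TestAgeProfile:
    def test_axis(self):
        p = AgeProfile.zeros(N)
        assert p.max_age == N
        assert len(p) == N + 1
        assert list(p.ages[:3]) == [0, 1, 2]

    def test_rejects_non_finite(self):
        with pytest.raises(InvalidInputError):
            AgeProfile(np.array([1.0, np.nan]))
        with pytest.raises(InvalidInputError):
            AgeProfile(np.array([np.inf]))

    def test_rejects_empty_and_2d(self):
        with pytest.raises(InvalidInputError):
            AgeProfile(np.zeros((2, 2)))
        with pytest.raises(InvalidInputError):
            AgeProfile(np.zeros(0))

    def test_values_frozen(self):
        p = AgeProfile.full(3, 1.0)
        with pytest.raises(ValueError):
            p.values[0] = 2.0

    def test_flavour_checks(self):
        signed = AgeProfile(np.array([-1.0, 2.0]))
        with pytest.raises(InvalidInputError):
            signed.require_amount()
        with pytest.raises(InvalidInputError):
            AgeProfile(np.array([0.5, 1.2])).require_participation()
        AgeProfile(np.array([0.0, 1.0])).require_participation()

    def test_arithmetic_axis_mismatch(self):
        with pytest.raises(InvalidInputError):
            AgeProfile.zeros(3) + AgeProfile.zeros(4)


class TestExpandGroupProfile:
    def test_single_covering_group(self):
        p = expand_group_profile([(0, 78, 100.0)], N)
        assert p.values.size == 79
        assert np.all(p.values == 100.0)

    def test_step_function_with_gap(self):
        p = expand_group_profile([(0, 4, 50.0), (5, 14, 20.0)], N)
        assert np.all(p.values[0:5] == 50.0)
        assert np.all(p.values[5:15] == 20.0)
        assert np.all(p.values[15:] == 0.0)

    def test_overlap_rejected(self):
        with pytest.raises(InvalidInputError, match="overlap"):
            expand_group_profile([(0, 10, 5.0), (8, 20, 7.0)], N)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            expand_group_profile([(70, 80, 1.0)], N)
        with pytest.raises(InvalidInputError):
            expand_group_profile([(-1, 5, 1.0)], N)

    def test_inverted_group_rejected(self):
        with pytest.raises(InvalidInputError):
            expand_group_profile([(10, 5, 1.0)], N)

    @given(
        st.lists(
            st.tuples(st.integers(0, 70), st.integers(1, 8), st.floats(0.1, 100.0)),
            min_size=1,
            max_size=6,
        )
    )
    def test_membership_property(self, raw):
        # build disjoint groups left to right, then check every age
        groups = []
        cursor = 0
        for start_off, width, amount in raw:
            lo = cursor + start_off % 5
            hi = lo + width
            if hi > N:
                break
            groups.append((lo, hi, amount))
            cursor = hi + 1
        if not groups:
            return
        p = expand_group_profile(groups, N)
        for age in range(N + 1):
            inside = [a for (lo, hi, a) in groups if lo <= age <= hi]
            assert p[age] == (inside[0] if inside else 0.0)


class TestPerCapitaProfile:
    def test_basic_division(self):
        p = per_capita_profile(1000.0, 10.0, 17, N)
        assert np.all(p.values[:17] == 0.0)
        assert np.all(p.values[17:] == 100.0)

    def test_zero_aggregate(self):
        p = per_capita_profile(0.0, 5.0, 0, N)
        assert np.all(p.values == 0.0)

    def test_boundary_start_age(self):
        p = per_capita_profile(500.0, 4.0, 78, N)
        assert p[78] == 125.0
        assert np.all(p.values[:78] == 0.0)

    def test_nonpositive_population(self):
        with pytest.raises(InvalidInputError):
            per_capita_profile(100.0, 0.0, 0, N)
        with pytest.raises(InvalidInputError):
            per_capita_profile(100.0, -2.0, 0, N)

    def test_start_age_out_of_range(self):
        with pytest.raises(InvalidInputError):
            per_capita_profile(100.0, 1.0, 79, N)


class TestWeightByParticipation:
    def test_scalar_product(self):
        out = weight_by_participation(AgeProfile.full(N, 200.0), AgeProfile.full(N, 0.5))
        assert np.all(out.values == 100.0)

    def test_absorbing_zero_and_identity(self):
        amount = AgeProfile(np.linspace(0, 50, N + 1))
        assert np.all(weight_by_participation(amount, AgeProfile.zeros(N)).values == 0.0)
        np.testing.assert_array_equal(
            weight_by_participation(amount, AgeProfile.full(N, 1.0)).values, amount.values
        )

    def test_participation_bounds_enforced(self):
        with pytest.raises(InvalidInputError):
            weight_by_participation(AgeProfile.full(N, 1.0), AgeProfile.full(N, 1.5))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25)
    def test_bounded_by_amount(self, seed):
        rng = np.random.default_rng(seed)
        amount = AgeProfile(rng.uniform(0, 100, N + 1))
        part = AgeProfile(rng.uniform(0, 1, N + 1))
        out = weight_by_participation(amount, part)
        assert np.all(out.values <= amount.values + 1e-12)


class TestProfileSets:
    def test_healthcare_participation_defaults_to_one(self):
        ts = make_transfer_set()
        assert np.all(ts.healthcare_part.values == 1.0)
        assert np.all(ts.pensions_part.values == 1.0)

    def test_axis_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            make_transfer_set(education_amount=AgeProfile.zeros(50))

    def test_tax_start_age_invariants(self):
        vat = np.zeros(N + 1)
        vat[10] = 5.0  # below the VAT starting age
        with pytest.raises(InvalidInputError, match="vat"):
            make_tax_set(vat=AgeProfile(vat))
        fuel = np.zeros(N + 1)
        fuel[12] = 1.0
        with pytest.raises(InvalidInputError, match="fuel"):
            make_tax_set(fuel=AgeProfile(fuel))
        other = np.zeros(N + 1)
        other[17] = 1.0
        with pytest.raises(InvalidInputError, match="other"):
            make_tax_set(other=AgeProfile(other))

    def test_negative_amount_rejected(self):
        bad = np.zeros(N + 1)
        bad[40] = -1.0
        with pytest.raises(InvalidInputError):
            make_tax_set(ss=AgeProfile(bad))


class TestSumTransfers:
    def test_all_zero(self):
        assert np.all(sum_transfers(make_transfer_set()).values == 0.0)

    def test_single_component_identity(self):
        amount = np.zeros(N + 1)
        amount[6:17] = 3000.0
        part = np.zeros(N + 1)
        part[6:17] = 1.0
        ts = make_transfer_set(
            education_amount=AgeProfile(amount), education_part=AgeProfile(part)
        )
        np.testing.assert_allclose(sum_transfers(ts).values, amount)

    def test_matches_per_age_loop(self, rng):
        ts = make_transfer_set(
            education_amount=AgeProfile(rng.uniform(0, 10, N + 1)),
            education_part=AgeProfile(rng.uniform(0, 1, N + 1)),
            unemp_amount=AgeProfile(rng.uniform(0, 10, N + 1)),
            unemp_part=AgeProfile(rng.uniform(0, 1, N + 1)),
        )
        # independent oracle: explicit per-age loop over the five components
        expected = []
        for age in range(N + 1):
            total = 0.0
            for name in ("education", "healthcare", "wages", "pensions", "unemp"):
                amount, part = ts.component(name)
                total += amount[age] * part[age]
            expected.append(total)
        np.testing.assert_allclose(sum_transfers(ts).values, expected, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 2.0])
    def test_linearity_in_amounts(self, rng, alpha):
        ts = make_transfer_set(
            education_amount=AgeProfile(rng.uniform(0, 10, N + 1)),
            education_part=AgeProfile(rng.uniform(0, 1, N + 1)),
            healthcare_amount=AgeProfile(rng.uniform(0, 10, N + 1)),
        )
        scaled = ts.scale_amounts(alpha)
        np.testing.assert_allclose(
            sum_transfers(scaled).values, alpha * sum_transfers(ts).values, rtol=1e-12
        )


class TestSumTaxes:
    def test_all_zero(self):
        assert np.all(sum_taxes(make_tax_set()).values == 0.0)

    def test_single_component_identity(self):
        ss = rngless = np.zeros(N + 1)
        ss = np.zeros(N + 1)
        ss[20:60] = 1234.5
        tset = make_tax_set(ss=AgeProfile(ss))
        np.testing.assert_array_equal(sum_taxes(tset).values, ss)

    def test_matches_per_age_loop(self, rng):
        kw = {}
        for name in ("ss", "income", "corporate", "nonresident", "alcohol", "tobacco"):
            kw[name] = AgeProfile(rng.uniform(0, 5, N + 1))
        tset = make_tax_set(**kw)
        expected = [
            sum(prof[age] for _, prof in tset.items()) for age in range(N + 1)
        ]
        np.testing.assert_allclose(sum_taxes(tset).values, expected, rtol=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 2.0])
    def test_linearity(self, rng, alpha):
        tset = make_tax_set(ss=AgeProfile(rng.uniform(0, 5, N + 1)))
        np.testing.assert_allclose(
            sum_taxes(tset.scale_amounts(alpha)).values,
            alpha * sum_taxes(tset).values,
            rtol=1e-12,
        )
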
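"""The six indices, rankings and the Spearman matrix against brute force."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ethnoquant.indices import (
    correlation_matrix,
    cultural_importance,
    fidelity_level,
    fidelity_table,
    icf,
    jaccard,
    rank_table,
    species_indices,
    use_diversity,
    use_value,
)
from ethnoquant.io import CitationRecord, round_half_up
from ethnoquant.simulate import CitationSimConfig, gen_citations, sim_study_config
from ethnoquant.usereports import collapse_citations, species_use_matrix


class TestUseValue:
    @pytest.mark.parametrize("ur,n,expected", [(1134, 335, 3.39), (53, 335, 0.16), (335, 335, 1.0)])
    def test_published_and_identity_cases(self, ur, n, expected):
        assert round_half_up(use_value(ur, n), 2) == expected

    def test_zero_informants_is_domain_error(self):
        with pytest.raises(ValueError):
            use_value(10, 0)


class TestCulturalImportance:
    def test_forced_by_formula(self):
        assert cultural_importance({1: 10, 2: 5}, 10) == pytest.approx(1.5)

    def test_every_citer_once_gives_one(self):
        assert cultural_importance({3: 7}, 7) == pytest.approx(1.0)

    def test_zero_informants_with_reports_rejected(self):
        with pytest.raises(ValueError):
            cultural_importance({1: 3}, 0)


class TestUseDiversity:
    def test_single_category_is_zero(self):
        assert use_diversity({9: 42}) == 0.0

    def test_uniform_four_categories(self):
        assert use_diversity({1: 5, 2: 5, 3: 5, 4: 5}) == pytest.approx(math.log(4))

    def test_three_one_split(self):
        # -(3/4 ln 3/4 + 1/4 ln 1/4) = 0.5623...
        assert use_diversity({1: 3, 2: 1}) == pytest.approx(0.562335, abs=1e-6)

    def test_needs_a_positive_count(self):
        with pytest.raises(ValueError):
            use_diversity({1: 0})


class TestICF:
    @pytest.mark.parametrize(
        "nur,nt,expected",
        [(3588, 61, 0.98), (6322, 82, 0.99), (7, 7, 0.0), (7, 1, 1.0)],
    )
    def test_published_and_endpoint_cases(self, nur, nt, expected):
        assert round_half_up(icf(nur, nt), 2) == expected

    def test_undefined_below_two_reports(self):
        with pytest.raises(ValueError):
            icf(1, 1)


class TestFidelityLevel:
    @pytest.mark.parametrize("ip,iu,expected", [(44, 45, 98), (158, 158, 100), (1, 100, 1)])
    def test_published_cases(self, ip, iu, expected):
        assert round_half_up(fidelity_level(ip, iu), 0) == expected

    def test_ip_above_iu_rejected(self):
        with pytest.raises(ValueError):
            fidelity_level(5, 4)


class TestJaccard:
    def test_identical_sets_paper_variant_is_half(self):
        assert jaccard({"a", "b"}, {"a", "b"}, "paper") == pytest.approx(0.5)

    def test_identical_sets_standard_variant_is_one(self):
        assert jaccard({"a", "b"}, {"a", "b"}, "standard") == pytest.approx(1.0)

    def test_disjoint_sets(self):
        assert jaccard({"a"}, {"b"}, "paper") == 0.0
        assert jaccard({"a"}, {"b"}, "standard") == 0.0

    def test_partial_overlap_both_variants(self):
        a, b = {"a", "b", "c"}, {"b", "c", "d"}
        assert jaccard(a, b, "paper") == pytest.approx(2 / 6)
        assert jaccard(a, b, "standard") == pytest.approx(0.5)

    def test_symmetric(self):
        a, b = {"a", "b", "c"}, {"b", "x"}
        for variant in ("paper", "standard"):
            assert jaccard(a, b, variant) == jaccard(b, a, variant)


class TestRankTable:
    def frame(self):
        return pd.DataFrame(
            {"species_id": ["c", "a", "b", "d"], "UV": [1.0, 3.0, 2.0, 2.0]}
        )

    def test_descending_with_name_tiebreak(self):
        out = rank_table(self.frame(), "UV", k=4)
        assert list(out["species_id"]) == ["a", "b", "d", "c"]

    def test_k_zero_empty(self):
        assert len(rank_table(self.frame(), "UV", k=0)) == 0

    def test_permutation_invariant(self):
        df = self.frame()
        shuffled = df.sample(frac=1, random_state=5)
        assert rank_table(df, "UV", 4).equals(rank_table(shuffled, "UV", 4))


class TestFidelityTable:
    def test_ip_iu_from_citations(self):
        cits = [
            CitationRecord("i1", "sp1", "fever", 14),
            CitationRecord("i2", "sp1", "fever", 14),
            CitationRecord("i2", "sp1", "cough", 8),
            CitationRecord("i3", "sp1", "cough", 8),
        ]
        tab = fidelity_table(cits).set_index("ailment")
        assert tab.loc["fever", "Ip"] == 2 and tab.loc["fever", "Iu"] == 3
        assert tab.loc["fever", "FL"] == pytest.approx(100 * 2 / 3)


def brute_force_indices(reports, n_total):
    """Independent recomputation of all per-species values from raw triples."""
    by_species = {}
    for r in reports:
        by_species.setdefault(r.species_id, []).append(r)
    rows = {}
    for sp, rs in by_species.items():
        cats = {}
        informants = set()
        for r in rs:
            cats[r.category] = cats.get(r.category, 0) + 1
            informants.add(r.informant_id)
        ur = len(rs)
        ps = [c / ur for c in cats.values()]
        rows[sp] = {
            "UR": ur,
            "UC": len(cats),
            "UV": ur / n_total,
            "CIV": ur / len(informants),
            "UD": -sum(p * math.log(p) for p in ps),
        }
    return rows


class TestAgainstBruteForce:
    def test_species_indices_match_brute_force_on_synthetic_data(self):
        cfg = CitationSimConfig(seed=3, n_informants=40, n_species=20, mean_citations=12)
        reports = collapse_citations(gen_citations(cfg))
        scfg = sim_study_config(cfg)
        table = species_indices(species_use_matrix(reports, scfg), scfg).set_index("species_id")
        expected = brute_force_indices(reports, scfg.n_informants_total)
        assert set(table.index) == set(expected)
        for sp, exp in expected.items():
            for col, val in exp.items():
                assert table.loc[sp, col] == pytest.approx(val, abs=1e-12), (sp, col)


def brute_force_spearman(x, y):
    """Midrank transform then Pearson — the definitional route."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = midranks(x), midranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestCorrelationMatrix:
    def synthetic_table(self, seed=5):
        cfg = CitationSimConfig(seed=seed, n_informants=30, n_species=18, mean_citations=10)
        reports = collapse_citations(gen_citations(cfg))
        scfg = sim_study_config(cfg)
        return species_indices(species_use_matrix(reports, scfg), scfg)

    def test_ur_uv_correlation_is_exactly_one(self):
        tab = self.synthetic_table()
        rho = correlation_matrix(tab)
        assert rho.loc["UR", "UV"] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_unit_diagonal(self):
        rho = correlation_matrix(self.synthetic_table())
        assert np.allclose(rho.values, rho.values.T, equal_nan=True)
        assert np.allclose(np.diag(rho.values), 1.0)

    def test_matches_brute_force_rank_pearson(self):
        tab = self.synthetic_table(seed=9)
        rho = correlation_matrix(tab)
        for a in ("UR", "UC", "CIV", "UD"):
            for b in ("UC", "UV", "UD"):
                if a == b:
                    continue
                expected = brute_force_spearman(tab[a].values, tab[b].values)
                assert rho.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_column_flagged_nan(self):
        tab = pd.DataFrame(
            {"species_id": list("abc"), "UR": [2, 3, 4], "UC": [1, 1, 1],
             "UV": [0.2, 0.3, 0.4], "CIV": [1.0, 1.5, 2.0], "UD": [0.0, 0.0, 0.0]}
        )
        with pytest.warns(UserWarning, match="zero-variance"):
            rho = correlation_matrix(tab)
        assert math.isnan(rho.loc["UR", "UD"])

    def test_needs_three_rows(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({c: [1, 2] for c in ("UR", "UC", "UV", "CIV", "UD")}))
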
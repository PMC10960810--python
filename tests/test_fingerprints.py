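import math

import numpy as np
import pytest

from icp import (
    class_fraction,
    common_alleles,
    deletion_size_summary,
    landscape,
    replicate_correlation,
)
from icp.saclassifier import SampleProfile


def profile_from(fractions_by_allele, classes, sample_id="s", n=10000):
    counts = {a: int(round(f * n)) for a, f in fractions_by_allele.items()}
    total = sum(counts.values())
    return SampleProfile(sample_id, counts, dict(classes), total, 0)


@pytest.fixture
def toy_profile():
    return profile_from(
        {"D:31-40": 0.5, "D:20-45": 0.3, "I:50:TT": 0.2},
        {"D:31-40": "PEPPR", "D:20-45": "MMEJ", "I:50:TT": "INSRT"},
    )


class TestLandscape:
    def test_uniform_profile_is_flat(self):
        p = profile_from(
            {f"D:{i}-{i+5}": 0.25 for i in range(1, 5)},
            {f"D:{i}-{i+5}": "DELET" for i in range(1, 5)},
        )
        df = landscape(p, top_n=10)
        assert np.allclose(df["fraction"], 0.25)

    def test_dominant_allele_step(self):
        p = profile_from(
            {"D:1-6": 0.85, "D:2-7": 0.10, "D:3-8": 0.05},
            {f"D:{i}-{i+5}": "DELET" for i in range(1, 4)},
        )
        df = landscape(p, top_n=2)
        assert df["fraction"].iloc[0] == pytest.approx(0.85)
        assert list(df["rank"]) == [1, 2]

    def test_monotone_non_increasing_for_random_profiles(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            k = int(rng.integers(2, 30))
            w = rng.dirichlet(np.ones(k))
            p = profile_from(
                {f"D:{i+1}-{i+9}": w[i] for i in range(k)},
                {f"D:{i+1}-{i+9}": "DELET" for i in range(k)},
            )
            fr = landscape(p, top_n=50)["fraction"].to_numpy()
            assert np.all(np.diff(fr) <= 1e-12)

    def test_invalid_top_n(self, toy_profile):
        with pytest.raises(ValueError):
            landscape(toy_profile, top_n=0)


class TestClassFraction:
    def test_top3_sums_per_class(self, toy_profile):
        cf = class_fraction(toy_profile, top_n=3)
        assert cf.fractions == pytest.approx(
            {"PEPPR": 0.5, "MMEJ": 0.3, "INSRT": 0.2, "DELET": 0.0, "WT": 0.0}
        )

    def test_all_wt(self):
        p = profile_from({"WT": 1.0}, {"WT": "WT"})
        cf = class_fraction(p, include_wt=True)
        assert cf.fractions["WT"] == pytest.approx(1.0)

    def test_exclude_wt_before_ranking(self):
        p = profile_from(
            {"WT": 0.6, "D:31-40": 0.3, "D:20-45": 0.1},
            {"WT": "WT", "D:31-40": "PEPPR", "D:20-45": "MMEJ"},
        )
        cf = class_fraction(p, top_n=1, include_wt=False)
        assert cf.fractions["PEPPR"] == pytest.approx(0.3)
        assert cf.fractions["WT"] == 0.0

    def test_sums_to_one_over_all_alleles(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            k = int(rng.integers(1, 20))
            w = rng.dirichlet(np.ones(k))
            labels = rng.choice(["WT", "PEPPR", "MMEJ", "DELET", "INSRT"], k)
            p = profile_from(
                {f"D:{i+1}-{i+9}": w[i] for i in range(k)},
                {f"D:{i+1}-{i+9}": labels[i] for i in range(k)},
            )
            cf = class_fraction(p)  # all alleles, WT included
            assert sum(cf.fractions.values()) == pytest.approx(1.0)

    def test_renormalized_top_n(self, toy_profile):
        cf = class_fraction(toy_profile, top_n=2, renormalize=True)
        assert sum(cf.fractions.values()) == pytest.approx(1.0)


class TestCommonAlleles:
    def test_identical_profiles_share_everything(self, toy_profile):
        other = profile_from(
            dict(toy_profile.fractions),
            dict(toy_profile.allele_class),
            sample_id="t",
        )
        shared, matrix = common_alleles([toy_profile, other])
        assert shared == set(toy_profile.allele_counts)
        assert matrix.fractions.shape == (3, 2)

    def test_disjoint_profiles(self):
        a = profile_from({"D:1-6": 1.0}, {"D:1-6": "DELET"}, "a")
        b = profile_from({"D:9-14": 1.0}, {"D:9-14": "DELET"}, "b")
        shared, matrix = common_alleles([a, b])
        assert shared == set() and matrix.empty

    def test_planted_shared_alleles(self):
        rng = np.random.default_rng(21)
        shared_ids = [f"D:{i*3+1}-{i*3+8}" for i in range(7)]
        profiles = []
        for s in range(3):
            ids = shared_ids + [f"I:{90+s}:A"]
            w = rng.dirichlet(np.ones(len(ids)))
            profiles.append(
                profile_from(
                    dict(zip(ids, w)),
                    {a: ("INSRT" if a.startswith("I") else "DELET") for a in ids},
                    sample_id=f"s{s}",
                )
            )
        shared, matrix = common_alleles(profiles)
        assert shared == set(shared_ids)
        assert matrix.fractions.shape == (7, 3)


class TestReplicateCorrelation:
    def test_identical_vectors(self, toy_profile):
        other = profile_from(
            dict(toy_profile.fractions), dict(toy_profile.allele_class), "t"
        )
        _, matrix = common_alleles([toy_profile, other])
        res = replicate_correlation(matrix, "s", "t")
        assert res.r2 == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        import pandas as pd

        df = pd.DataFrame({"a": [0.1, 0.2, 0.3], "b": [0.3, 0.2, 0.1]})
        res = replicate_correlation(df, "a", "b")
        assert res.r == pytest.approx(-1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_closed_form_oracle(self):
        import pandas as pd

        x = np.array([0.5, 0.3, 0.2])
        y = np.array([0.4, 0.4, 0.2])
        res = replicate_correlation(pd.DataFrame({"a": x, "b": y}), "a", "b")
        # independent closed form: r = cov / (sx sy)
        dx, dy = x - x.mean(), y - y.mean()
        r_manual = (dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum())
        assert res.r == pytest.approx(r_manual)
        assert res.r2 == pytest.approx(r_manual**2)
        assert res.r2 == pytest.approx(4 / 7)

    def test_symmetry_and_scale_invariance(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        x, y = rng.random(8), rng.random(8)
        df = pd.DataFrame({"a": x, "b": y, "a2": 3.5 * x, "b2": 3.5 * y})
        r_ab = replicate_correlation(df, "a", "b")
        r_ba = replicate_correlation(df, "b", "a")
        r_scaled = replicate_correlation(df, "a2", "b2")
        assert r_ab.r == pytest.approx(r_ba.r)
        assert r_ab.r == pytest.approx(r_scaled.r)

    def test_zero_variance_flagged(self):
        import pandas as pd

        df = pd.DataFrame({"a": [0.2, 0.2, 0.2], "b": [0.1, 0.5, 0.4]})
        res = replicate_correlation(df, "a", "b")
        assert res.undefined and math.isnan(res.r)

    def test_too_few_alleles(self):
        import pandas as pd

        df = pd.DataFrame({"a": [0.2, 0.8], "b": [0.1, 0.9]})
        with pytest.raises(ValueError):
            replicate_correlation(df, "a", "b")


class TestDeletionSizeSummary:
    def _matrix(self, ids, classes):
        import pandas as pd

        from icp.fingerprints import AlleleFeatureMatrix
        from icp import parse_allele_id

        edits = {a: parse_allele_id(a) for a in ids}
        return AlleleFeatureMatrix(
            pd.DataFrame({"s": [1 / len(ids)] * len(ids)}, index=ids),
            classes,
            {a: e.del_len for a, e in edits.items()},
            {a: len(e.insertion) for a, e in edits.items()},
        )

    def test_mean_deletion_length(self):
        m = self._matrix(["D:11-20", "D:11-30"], {"D:11-20": "DELET", "D:11-30": "DELET"})
        df = deletion_size_summary(m, {"D:11-20": 1, "D:11-30": 1})
        assert df["mean_del_len"].iloc[0] == pytest.approx(15.0)

    def test_insert_only_cluster_flagged(self):
        m = self._matrix(["I:40:TTA"], {"I:40:TTA": "INSRT"})
        df = deletion_size_summary(m, {"I:40:TTA": "c1"})
        assert df["no_deletions"].iloc[0]
        assert math.isnan(df["mean_del_len"].iloc[0])
        assert df["mean_ins_len"].iloc[0] == pytest.approx(3.0)

    def test_planted_cluster_means_recovered(self):
        ids = [f"D:1-{10+i}" for i in range(4)] + [f"D:1-{30+i}" for i in range(4)]
        classes = {a: "PEPPR" for a in ids}
        m = self._matrix(ids, classes)
        assignment = {a: ("mini" if int(a.split("-")[1]) < 20 else "midi") for a in ids}
        df = deletion_size_summary(m, assignment).set_index("cluster")
        assert df.loc["mini", "mean_del_len"] == pytest.approx(np.mean([10, 11, 12, 13]))
        assert df.loc["midi", "mean_del_len"] == pytest.approx(np.mean([30, 31, 32, 33]))
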
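import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from zframan.bands import (
    BandClusterer,
    annotate_bands,
    annotation_frame,
    cluster_band_frequencies,
    presence_table,
    retain_bands,
)
from zframan.synth import CANONICAL_FREQUENCIES


def comp_frame(F_values, organ="iris", animals=None, stage=96):
    n = len(F_values)
    animals = animals or [f"a{i % 6}" for i in range(n)]
    return pd.DataFrame(
        {
            "file": [f"f{i}.txt" for i in range(n)],
            "organ": organ,
            "animal_id": animals,
            "clutch_id": "c1",
            "stage_hpf": stage,
            "replicate": 1,
            "component_index": 0,
            "F": F_values,
            "W": 20.0,
            "A": 100.0,
            "amplitude": 1.0,
        }
    )


class TestClustering:
    def test_well_separated(self):
        clus = BandClusterer(delta=10.0).fit([979.0, 981.0, 1408.0, 1410.0])
        assert clus.band_labels_ == ["980", "1409"]
        assert list(clus.labels_) == [0, 0, 1, 1]

    def test_chaining(self):
        clus = BandClusterer(delta=10.0).fit([1000.0, 1009.0, 1018.0, 1027.0])
        assert len(clus.band_labels_) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_the_24_canonical_bands(self, seed):
        # fit jitter on real deconvolutions is well below 1 cm^-1; at that
        # scale the gap clustering always recovers the 24 planted bands
        # (labels match to the +-1 rounding of the empirical median)
        F = np.random.default_rng(seed).normal(
            np.repeat(CANONICAL_FREQUENCIES, 42), 1.0
        )
        clus = BandClusterer(delta=10.0).fit(F)
        labs = sorted(int(l) for l in clus.band_labels_)
        assert len(labs) == 24
        assert max(abs(a - b) for a, b in zip(labs, sorted(CANONICAL_FREQUENCIES))) <= 1

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(list(range(12))))
    def test_permutation_invariant(self, perm):
        F = np.array([500.0, 502.0, 700.0, 703.0, 705.0, 900.0,
                      1200.0, 1203.0, 1500.0, 1501.0, 1502.0, 1800.0])
        base = BandClusterer(delta=10.0).fit(F)
        shuf = BandClusterer(delta=10.0).fit(F[perm])
        # partition must be identical: compare cluster index per original item
        inv = np.empty(len(perm), dtype=int)
        inv[list(perm)] = np.arange(len(perm))
        assert list(base.cluster_centers_) == list(shuf.cluster_centers_)
        np.testing.assert_array_equal(base.labels_, shuf.labels_[inv])

    def test_empty_input(self):
        registry, df = cluster_band_frequencies(comp_frame([]).iloc[0:0])
        assert registry == []


class TestPresence:
    def _manifest(self, n_animals=6, organ="iris", stage=96):
        return pd.DataFrame(
            {
                "file": [f"m{i}.txt" for i in range(n_animals)],
                "animal_id": [f"a{i}" for i in range(n_animals)],
                "clutch_id": "c1",
                "organ": organ,
                "stage_hpf": stage,
                "replicate": 1,
            }
        )

    def test_four_of_six_animals(self):
        comp = comp_frame([1000.0] * 4, animals=[f"a{i}" for i in range(4)])
        _, lab = cluster_band_frequencies(comp)
        pres = presence_table(lab, self._manifest())
        assert pres["fraction"].iloc[0] == pytest.approx(4 / 6)

    def test_full_presence(self):
        comp = comp_frame([1000.0] * 6, animals=[f"a{i}" for i in range(6)])
        _, lab = cluster_band_frequencies(comp)
        pres = presence_table(lab, self._manifest())
        assert (pres["fraction"] == 1.0).all()

    def test_replicates_count_once(self):
        # one animal measured three times still counts as one presence
        comp = comp_frame([1000.0] * 3, animals=["a0", "a0", "a0"])
        comp["replicate"] = [1, 2, 3]
        _, lab = cluster_band_frequencies(comp)
        pres = presence_table(lab, self._manifest())
        assert pres["fraction"].iloc[0] == pytest.approx(1 / 6)

    def test_planted_three_of_six(self):
        comp = comp_frame([1409.0] * 3, animals=["a0", "a2", "a4"])
        _, lab = cluster_band_frequencies(comp)
        pres = presence_table(lab, self._manifest())
        assert pres["fraction"].iloc[0] == pytest.approx(0.5)


class TestRetention:
    def _presence(self, fractions, organ="iris", band="1000", n=6):
        return pd.DataFrame(
            {
                "organ": organ,
                "stage_hpf": [24 + 24 * i for i in range(len(fractions))],
                "band": band,
                "fraction": fractions,
                "n_present": [int(round(f * n)) for f in fractions],
                "n_animals": n,
            }
        )

    def test_one_stage_above_threshold_retains(self):
        ret = retain_bands(self._presence([0.5, 4 / 6, 1 / 3]))
        assert ret["iris"] == ["1000"]

    def test_exactly_sixty_percent_not_retained(self):
        ret = retain_bands(self._presence([0.6, 0.6, 0.6]))
        assert ret["iris"] == []

    def test_monotone_in_threshold(self):
        pres = pd.concat(
            [self._presence([0.5, 0.7], band="1000"), self._presence([0.9, 0.95], band="2000")],
            ignore_index=True,
        )
        sizes = [
            len(retain_bands(pres, threshold=t)["iris"]) for t in (0.3, 0.6, 0.8, 0.95)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_planted_true_and_noise_bands(self):
        frames = []
        for b in CANONICAL_FREQUENCIES:  # 24 well-represented bands
            frames.append(self._presence([5 / 6, 1.0], band=str(b)))
        for i, b in enumerate(range(4000, 4010)):  # 10 poorly present bands
            frames.append(self._presence([1 / 6, 2 / 6], band=str(b)))
        ret = retain_bands(pd.concat(frames, ignore_index=True))
        assert sorted(ret["iris"], key=float) == [str(b) for b in CANONICAL_FREQUENCIES]


class TestAnnotations:
    @pytest.mark.parametrize(
        "band,needle",
        [
            ("980", "symmetric stretching of phosphate"),
            ("1199", "amide III"),
            ("1409", "CH bending"),
            ("2929", "CH stretching"),
            ("1002", "phenylalanine"),
            ("796", "O-P-O"),
            ("3431", "O-H stretching"),
            ("1639", "amide I"),
            ("9999", "no literature assignment"),
        ],
    )
    def test_assignments(self, band, needle):
        (ann,) = annotate_bands([band])
        assert needle in ann.assignment

    def test_all_24_have_annotations(self):
        df = annotation_frame([str(b) for b in CANONICAL_FREQUENCIES])
        assert len(df) == 24
        assert (df["assignment"] != "no literature assignment").all()
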
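import numpy as np
import pandas as pd
import pytest

from apmsquant.errors import AmbiguousPeptideError, ApmsError, UnmappablePeptideError
from apmsquant.phospho import (
    compare_site_occupancy,
    discover_sites,
    locate_peptide,
    map_modifications_to_sites,
    occupancy_profile,
    site_occupancy,
    summarize_profile,
)
from apmsquant.simulate import PhosphoSiteSpec, SimulationConfig, simulate_experiment
from conftest import make_psm_frame


def beta3_like_sequence(length=430, sites=((408, "S"), (409, "S"), (322, "T"))):
    rng = np.random.default_rng(123)
    letters = list("".join(rng.choice(list("ACDEFGHIKLMNPQRVW"), size=length)))
    for idx, letter in sites:
        letters[idx - 1] = letter
    return "".join(letters)


class TestMapping:
    def test_phospho_offset_maps_to_reference_residue(self):
        seq = beta3_like_sequence()
        peptide = seq[400:415]  # residues 401..415
        psms = make_psm_frame([("r1", "bait", "B3", peptide, "phospho@8", 1.0)])
        sites = map_modifications_to_sites(next(psms.itertuples(index=False)), {"B3": seq})
        assert [s.label for s in sites] == ["S408"]

    def test_first_residue_of_peptide(self):
        seq = beta3_like_sequence()
        peptide = seq[321:333]  # starts at residue 322, a threonine
        psms = make_psm_frame([("r1", "bait", "B3", peptide, "phospho@1", 1.0)])
        sites = map_modifications_to_sites(next(psms.itertuples(index=False)), {"B3": seq})
        assert [s.label for s in sites] == ["T322"]

    def test_non_phospho_modifications_ignored(self):
        psms = make_psm_frame([("r1", "bait", "P", "KTSA", "oxidation@2", 1.0)])
        assert map_modifications_to_sites(next(psms.itertuples(index=False)), {"P": "MKTSA"}) == []

    def test_unmappable_and_ambiguous_peptides(self):
        with pytest.raises(UnmappablePeptideError):
            locate_peptide("XYZ", "MKTSA")
        with pytest.raises(AmbiguousPeptideError):
            locate_peptide("AB", "ABCAB")
        assert locate_peptide("KTS", "MKTSA") == 2


class TestSiteOccupancy:
    def make_run(self, n_phos, n_unmod, seq, start=401, site_offset=8):
        peptide = seq[start - 1 : start + 14]
        rows = [("r1", "bait", "B3", peptide, f"phospho@{site_offset}", 1.0)] * n_phos
        rows += [("r1", "bait", "B3", peptide, "", 1.0)] * n_unmod
        return make_psm_frame(rows)

    def test_counting_oracle(self):
        seq = beta3_like_sequence()
        psms = self.make_run(3, 7, seq)
        occ = site_occupancy(psms, "B3", 408, {"B3": seq})
        assert (occ.n_phos, occ.n_total) == (3, 10)
        assert occ.occupancy == pytest.approx(0.3)
        assert occ.label == "S408"

    def test_fully_phosphorylated_site(self):
        seq = beta3_like_sequence()
        occ = site_occupancy(self.make_run(4, 0, seq), "B3", 408, {"B3": seq})
        assert occ.occupancy == 1.0

    def test_uncovered_site_reported_not_covered(self):
        seq = beta3_like_sequence()
        occ = site_occupancy(self.make_run(2, 2, seq), "B3", 322, {"B3": seq})
        assert not occ.covered and occ.occupancy is None

    def test_phospho_elsewhere_counts_as_dephosphorylated_here(self):
        seq = beta3_like_sequence()
        peptide = seq[400:415]
        psms = make_psm_frame(
            [
                ("r1", "bait", "B3", peptide, "phospho@8", 1.0),  # S408
                ("r1", "bait", "B3", peptide, "phospho@9", 1.0),  # S409 only
            ]
        )
        occ = site_occupancy(psms, "B3", 408, {"B3": seq})
        assert (occ.n_phos, occ.n_total) == (1, 2)

    def test_peptide_count_mode_collapses_spectra(self):
        seq = beta3_like_sequence()
        psms = self.make_run(3, 7, seq)  # one peptide sequence, both states
        occ = site_occupancy(psms, "B3", 408, {"B3": seq}, count_mode="peptide")
        assert (occ.n_phos, occ.n_total) == (1, 1)
        with pytest.raises(ApmsError, match="count_mode"):
            site_occupancy(psms, "B3", 408, {"B3": seq}, count_mode="spectra")

    def test_intensities_do_not_affect_occupancy(self):
        seq = beta3_like_sequence()
        psms = self.make_run(3, 7, seq)
        boosted = psms.copy()
        boosted["intensity"] = boosted["intensity"] * 1e6
        a = site_occupancy(psms, "B3", 408, {"B3": seq})
        b = site_occupancy(boosted, "B3", 408, {"B3": seq})
        assert (a.n_phos, a.n_total) == (b.n_phos, b.n_total)


class TestProfiles:
    def test_discovery_and_summary_from_simulated_runs(self):
        config = SimulationConfig(
            seed=21,
            bait_proteins={"B3": 5.0},
            interactors={},
            n_background=3,
            dropout=0.0,
            phospho_sites=(
                PhosphoSiteSpec("B3", 40, 0.7, "S"),
                PhosphoSiteSpec("B3", 80, 0.3, "T"),
            ),
            psm_rate_overrides={"B3": 200.0},
        )
        exp = simulate_experiment(config)
        assert discover_sites(exp.psms, "B3", exp.proteome) == [40, 80]
        profile = occupancy_profile(exp.psms, "B3", exp.proteome)
        # mapping consistency: reported letter always matches the reference
        for rec in profile.itertuples(index=False):
            assert exp.proteome["B3"][rec.residue_index - 1] == rec.residue_letter
        summary = summarize_profile(profile).set_index("site_label")
        # ~110 covering PSMs per site over the 5 runs: 3 binomial SEs ~ 0.13
        assert summary.loc["S40", "mean_occupancy"] == pytest.approx(0.7, abs=0.15)
        assert summary.loc["T80", "mean_occupancy"] == pytest.approx(0.3, abs=0.15)


class TestComparison:
    def test_equal_groups_and_tiny_groups(self):
        res = compare_site_occupancy([0.5, 0.55, 0.6], [0.5, 0.55, 0.6])
        assert res.t == 0 and res.p == pytest.approx(1.0)
        with pytest.raises(ApmsError, match=">= 2"):
            compare_site_occupancy([0.5], [0.5, 0.6])
        with pytest.raises(ApmsError, match="no covered runs"):
            compare_site_occupancy([np.nan], [0.5, 0.6])

    def test_genotype_difference_recovered_in_monte_carlo(self):
        # per-run occupancies arise from ~200 covering PSMs; a 0.54 vs 0.63
        # difference over 5 + 5 runs should be called at alpha = 0.05 in the
        # vast majority of repetitions
        def occupancies(seed, theta):
            config = SimulationConfig(
                seed=seed,
                bait_proteins={"B3": 1.0},
                interactors={},
                n_background=0,
                n_control_runs=0,
                dropout=0.0,
                count_model="fixed",
                psms_per_protein=200.0,
                protein_length=18,
                peptide_length=12,
                phospho_sites=(PhosphoSiteSpec("B3", 7, theta, "S"),),
            )
            exp = simulate_experiment(config)
            profile = occupancy_profile(exp.psms, "B3", exp.proteome, residue_indices=[7])
            return profile["occupancy"].to_numpy()

        hits = 0
        n_reps = 200
        for rep in range(n_reps):
            wt = occupancies(2 * rep, 0.54)
            mut = occupancies(2 * rep + 1, 0.63)
            assert len(wt) == len(mut) == 5
            if compare_site_occupancy(wt, mut).p < 0.05:
                hits += 1
        assert hits / n_reps >= 0.90
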
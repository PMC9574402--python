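import pandas as pd
import pytest

from apmsquant.io import validate_psm_frame


def make_psm_frame(rows):
    """Build a validated PSM frame from (run_id, condition, protein, peptide, mods, intensity)."""
    df = pd.DataFrame(
        [
            {
                "spectrum_id": f"{run}:scan{i + 1:04d}",
                "run_id": run,
                "condition": cond,
                "bait_label": "Gabra1-IP" if cond == "bait" else "IgG",
                "genotype": "WT",
                "band": "250kDa",
                "protein": protein,
                "peptide": peptide,
                "modifications": mods,
                "intensity": intensity,
            }
            for i, (run, cond, protein, peptide, mods, intensity) in enumerate(rows)
        ]
    )
    return validate_psm_frame(df)


@pytest.fixture
def toy_run():
    """The two-protein single-run fixture: raw indices A=40, B=100."""
    return make_psm_frame(
        [
            ("r1", "bait", "A", "AAAA", "", 10.0),
            ("r1", "bait", "A", "AAAG", "", 30.0),
            ("r1", "bait", "B", "CCCC", "", 60.0),
            ("r1", "bait", "B", "CCCG", "", 40.0),
        ]
    )
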
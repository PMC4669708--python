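import numpy as np
import pandas as pd
import pytest


def make_psms(rows):
    """Build a PSM frame from compact tuples.

    Each row: (spectrum_id, peptide, proteins, engine, score) with
    optional trailing (decoy, condition, replicate).  Masses default to
    perfectly calibrated values.
    """
    records = []
    for r in rows:
        sid, pep, prots, engine, score = r[:5]
        decoy = r[5] if len(r) > 5 else False
        cond = r[6] if len(r) > 6 else "non_competed"
        rep = r[7] if len(r) > 7 else 0
        theo = 800.0 + 10.0 * (hash(pep) % 50)
        records.append(
            dict(spectrum_id=sid, peptide=pep, proteins=prots, engine=engine,
                 score=float(score), decoy=decoy, condition=cond, replicate=rep,
                 precursor_measured=theo, precursor_theoretical=theo,
                 fragment_pairs=[(200.0, 200.0), (300.0, 300.0)], missed_cleavages=0)
        )
    return pd.DataFrame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
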
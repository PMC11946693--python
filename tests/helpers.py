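"""Shared test helpers."""

import numpy as np

from diolconf.state_series import MISSING, StateSeries


def make_series(columns, stride=1.0):
    """Build a StateSeries from per-molecule canonical-label sequences."""
    from diolconf.conformation_space import ConformationLabel, canonicalize, family_of

    n_mol = len(columns)
    n_frames = len(columns[0])
    can = np.empty((n_frames, n_mol), dtype=object)
    fam = np.empty((n_frames, n_mol), dtype=object)
    for m, seq in enumerate(columns):
        for f, name in enumerate(seq):
            if name == MISSING:
                can[f, m] = fam[f, m] = MISSING
            else:
                lbl = canonicalize(ConformationLabel.parse(name))
                can[f, m] = str(lbl)
                fam[f, m] = family_of(lbl)
    return StateSeries(
        stride_ps=stride,
        times=np.arange(n_frames) * stride,
        raw=can.copy(),
        canonical=can,
        family=fam,
    )
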
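"""Optional adapters for common EEG interchange formats.

Isolated from the core pipeline: nothing else in the package imports this
module, and the MNE readers are only touched when an adapter is called.
Use these to feed externally recorded data (e.g. BrainVision triplets or
EEGLAB .set files) into :func:`oscimap.preprocess.run_pipeline`.
"""

from __future__ import annotations

import numpy as np

from .montage import standard_layout
from .synth import EEGRecording


def _from_mne_raw(raw, subject_id: str, cohort: str, session=None) -> EEGRecording:
    layout = standard_layout()
    missing = [n for n in layout.names if n not in raw.ch_names]
    if missing:
        raise ValueError(f"recording lacks required channels: {missing[:5]}...")
    raw = raw.copy().pick(list(layout.names)).reorder_channels(list(layout.names))
    data = raw.get_data() * 1e6  # volts -> microvolts
    return EEGRecording(
        data=np.asarray(data, dtype=float), rate=float(raw.info["sfreq"]),
        layout=layout, subject_id=subject_id, cohort=cohort, session=session,
        bad_channels=tuple(raw.info["bads"]),
    )


def read_brainvision(vhdr_path, subject_id: str, cohort: str, session=None) -> EEGRecording:
    """Load a BrainVision header/marker/data triplet."""
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return _from_mne_raw(raw, subject_id, cohort, session)


def read_eeglab(set_path, subject_id: str, cohort: str, session=None) -> EEGRecording:
    """Load an EEGLAB .set recording."""
    import mne

    raw = mne.io.read_raw_eeglab(set_path, preload=True, verbose="error")
    return _from_mne_raw(raw, subject_id, cohort, session)
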
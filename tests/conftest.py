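import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mirameta.corpus import MicroRNAName, StudyCorpus, SubStudyRecord
from mirameta.meta import EffectSize


def make_effects(ys, vs, parents=None):
    """EffectSize list from parallel y / v sequences."""
    if np.isscalar(vs):
        vs = [vs] * len(ys)
    parents = parents or [f"study{i}" for i in range(len(ys))]
    return [EffectSize(float(y), float(v), False, f"sub{i}", parents[i])
            for i, (y, v) in enumerate(zip(ys, vs))]


def make_record(substudy_id="s1", parent="p1", mirna="miR-1-3p", tissue_class="blood",
                fraction="serum", platform="pcr", n_case=10, n_ctrl=10,
                events_case=5, events_ctrl=5, direction="up"):
    return SubStudyRecord(
        substudy_id=substudy_id, parent_study_id=parent,
        mirna=MicroRNAName(mirna, mirna, "exact"),
        tissue_raw=fraction if tissue_class == "blood" else tissue_class,
        tissue_class=tissue_class, blood_fraction=fraction,
        platform=platform, n_case=n_case, n_ctrl=n_ctrl,
        events_case=events_case, events_ctrl=events_ctrl,
        reported_direction=direction)


@pytest.fixture
def two_mirna_corpus():
    """Two microRNAs x three substudies each; one clear effect, one null."""
    records = []
    for i, (ec, et) in enumerate([(8, 2), (9, 3), (7, 2)]):
        records.append(make_record(substudy_id=f"a{i}", parent=f"pa{i}", mirna="miR-10a-5p",
                                   events_case=ec, events_ctrl=et))
    for i, (ec, et) in enumerate([(5, 5), (4, 6), (6, 5)]):
        records.append(make_record(substudy_id=f"b{i}", parent=f"pb{i}", mirna="miR-20b-5p",
                                   events_case=ec, events_ctrl=et))
    return StudyCorpus(records)
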
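import numpy as np
import pytest

from mqtlkit.consensus_map import GeneticMap, merge_maps, project_qtl
from mqtlkit.qtl_compendium import QTLRecord
from mqtlkit.synthetic_data import SimulationConfig, simulate_qtl_panel


def make_qtl(qtl_id="q1", chrom=1, peak=20.0, ci=(18.0, 22.0), pve=0.1,
             pop_type="RIL", pop_size=200, markers=("mL", "mR"),
             map_id="mapA", lod=3.0):
    return QTLRecord(
        qtl_id=qtl_id, study_id="S1", trait="drought tolerance",
        chromosome=chrom, peak_cm=peak,
        ci_low_cm=None if ci is None else ci[0],
        ci_high_cm=None if ci is None else ci[1],
        lod=lod, pve=pve, population_type=pop_type, population_size=pop_size,
        flanking_markers=markers, map_id=map_id,
    )


@pytest.fixture
def simple_map():
    return GeneticMap("mapA", [
        ("mL", 1, 10.0), ("mM", 1, 15.0), ("mR", 1, 20.0),
    ])


@pytest.fixture
def one_chrom_panel():
    """60 QTLs from 3 planted loci on one chromosome, projected."""
    cfg = SimulationConfig(seed=11, n_chromosomes=1, qtls_per_locus=(20, 20))
    panel = simulate_qtl_panel(cfg)
    consensus = merge_maps(panel.maps)
    by_id = {m.map_id: m for m in panel.maps}
    projected = [project_qtl(q, by_id[q.map_id], consensus) for q in panel.qtls]
    return cfg, panel, projected


@pytest.fixture
def rng():
    return np.random.default_rng(42)
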
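import numpy as np
import pandas as pd
import pytest

import dualmeth as dm


def make_annotation(records):
    """Annotation frame from (probe_id, chrom, pos, gene_entries, island) tuples."""
    df = pd.DataFrame(
        {
            "chrom": [r[1] for r in records],
            "pos": [r[2] for r in records],
            "gene_entries": [tuple(r[3]) for r in records],
            "island_relation": [r[4] for r in records],
            "intergenic": [len(r[3]) == 0 for r in records],
        },
        index=pd.Index([r[0] for r in records], name="probe_id"),
    )
    return df


@pytest.fixture(scope="session")
def small_dataset():
    """A modest paired BS/TAB dataset with mixed 5mC/5hmC-driven effects."""
    cfg = dm.SimulationConfig(
        n_probes=4000, n_chrom=2, effect_size=3.0, frac_hmc_driven=0.5, seed=17
    )
    return dm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Zero-effect dataset without confounders or batch structure."""
    cfg = dm.SimulationConfig(
        n_probes=10_000,
        effect_size=0.0,
        n_latent=0,
        confounder_sd=0.0,
        batch_sd=0.0,
        detection_fail_rate=0.0,
        seed=22,
    )
    return dm.simulate_dataset(cfg)


@pytest.fixture()
def tiny_manifest(tmp_path):
    path = tmp_path / "manifest.csv"
    path.write_text(
        "IlmnID,CHR,MAPINFO,UCSC_RefGene_Name,UCSC_RefGene_Group,Relation_to_UCSC_CpG_Island\n"
        "cg01,7,1000,RELN,Body,Island\n"
        "cg02,1,50,,,\n"
        "cgX,1,60,A;B,TSS200;Body,N_Shore\n"
        "cg03,2,500,GAD1,5'UTR,S_Shelf\n"
    )
    return path
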
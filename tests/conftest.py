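import pytest

from strucmap import fixtures as fx
from strucmap.pipeline import RunConfig


@pytest.fixture(scope="session")
def demo_workspace(tmp_path_factory):
    """The three-structure demo workspace with its run config.

    FX1A: high-quality drug-bound complex, full coverage.
    FX2B: lower-resolution apo structure with an unresolved loop.
    FX3C: eleven engineered mutations (must be filtered).
    """
    root = tmp_path_factory.mktemp("demo")
    info = fx.make_demo_workspace(root, seed=0)
    cfg = RunConfig(
        structures_dir=info["paths"]["structures_dir"],
        reference_fasta=info["paths"]["reference_fasta"],
        msa_path=info["paths"]["msa"],
        variant_table=info["paths"]["variant_table"],
        ligand_dict=info["paths"]["ligand_dict"],
        remark_table=info["paths"]["remark_table"],
        output_dir=str(root / "out"),
        target_chain_ids=["A"],
    )
    return {"root": root, "info": info, "cfg": cfg}


@pytest.fixture()
def simple_structure_paths(tmp_path):
    """One 30-residue chain, one STI ligand, five waters — known counts."""
    spec = fx.FixtureSpec(
        seed=7, ref_length=30, entry_id="SIMP",
        ligands=[fx.LigandFixture("STI", (8.0, 0.0, 20.0))],
        n_waters=5,
    )
    ref = fx.make_reference(spec)
    paths, gt = fx.make_structure(spec, ref, tmp_path, ("pdb", "mmcif"))
    return paths, ref, gt
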
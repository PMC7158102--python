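import pytest

import tarpan
from tarpan.fixtures import SimulationConfig, generate_all


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11, blacklist_genes=("U2AF1",))


@pytest.fixture(scope="session")
def fixture_paths(sim_config, tmp_path_factory):
    return generate_all(sim_config, tmp_path_factory.mktemp("inputs"))


@pytest.fixture(scope="session")
def populated_db(sim_config, fixture_paths, tmp_path_factory):
    """One database with a fully imported sample, shared read-mostly."""
    db_path = tmp_path_factory.mktemp("db") / "panel.sqlite"
    db = tarpan.create_database(
        "fixture-panel", "hg38", "v1",
        fixture_paths["targets_bed"], fixture_paths["groups_bed"],
        fixture_paths["blacklist_bed"], out_path=db_path,
    )
    tarpan.register_sample(db, "S1")
    tarpan.import_depths(
        db, "S1", fixture_paths["tumor_table"], fixture_paths["normal_table"]
    )
    tarpan.import_small_variants(db, "S1", fixture_paths["snv_vcf"])
    tarpan.import_structural_variants(db, "S1", fixture_paths["sv_vcf"])
    tarpan.import_snp_records(db, "S1", fixture_paths["snp_table"])
    yield db
    db.close()


def write_bed(path, rows):
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture
def tiny_db(tmp_path):
    """3-target, 2-group panel on two chromosomes; no blacklist."""
    targets = write_bed(
        tmp_path / "t.bed",
        [("chr1", 100, 200, "GENEA"), ("chr1", 300, 400, "GENEA"),
         ("chr2", 100, 200, "GENEB")],
    )
    groups = write_bed(
        tmp_path / "g.bed",
        [("chr1", 100, 400, "GENEA"), ("chr2", 100, 200, "GENEB")],
    )
    db = tarpan.create_database(
        "tiny", "hg38", "v0", targets, groups, out_path=tmp_path / "tiny.sqlite"
    )
    yield db
    db.close()


def write_depth_table(path, rows, extra_col=None):
    header = "chromosome\tstart\tend\tdepth"
    if extra_col:
        header += f"\t{extra_col}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path
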
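"""Table round-trips, schema validation, pipeline determinism and CLI."""

import filecmp

import pandas as pd
import pytest
from click.testing import CliRunner

from cystivar.cli import main as cli_main
from cystivar.pipeline import run_pipeline
from cystivar.severity import Method
from cystivar.synthetic_data import SimulationConfig, simulate
from cystivar.tables import (
    PATIENT_COLUMNS,
    TableFormatError,
    VARIANT_COLUMNS,
    read_patient_table,
    read_variant_table,
    variants_to_frame,
    write_patient_table,
    write_variant_table,
)


@pytest.fixture(scope="module")
def simulated_files(tmp_path_factory):
    base = tmp_path_factory.mktemp("sim")
    variants, patients = simulate(SimulationConfig(seed=31))
    write_variant_table(variants, base / "variants.tsv")
    write_patient_table(patients, base / "patients.tsv")
    return base / "variants.tsv", base / "patients.tsv", variants, patients


class TestVariantTable:
    def test_round_trip_preserves_records(self, simulated_files, tmp_path):
        path, _, variants, _ = simulated_files
        records = read_variant_table(path)
        assert len(records) == len(variants)
        rewritten = tmp_path / "again.tsv"
        write_variant_table(variants_to_frame(records), rewritten)
        assert filecmp.cmp(path, rewritten, shallow=False)

    def test_nulls_round_trip_as_empty_strings(self, tmp_path):
        df = pd.DataFrame([{
            "gene": "SLC7A9", "hgvs_p": "p.Val142Ala",
            "consequence": "missense", "allele_frequency": "",
            "consurf": 1, "ddg": "", "sift": 0.2, "polyphen2": "",
            "mutation_assessor": "", "fathmm": "", "condel": "", "cadd": "",
            "disease_associated": True,
        }], columns=list(VARIANT_COLUMNS))
        path = tmp_path / "v.tsv"
        write_variant_table(df, path)
        [record] = read_variant_table(path)
        assert record.allele_frequency is None
        assert record.ddg is None
        assert record.predictor_scores == {"sift": 0.2}

    def test_out_of_range_consurf_rejected_with_row(self, tmp_path):
        df = pd.DataFrame([{c: "" for c in VARIANT_COLUMNS}])
        df.loc[0, ["gene", "hgvs_p", "consequence", "consurf",
                   "disease_associated"]] = \
            ["SLC7A9", "p.Val142Ala", "missense", "10", "true"]
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(TableFormatError, match="row 1.*consurf"):
            read_variant_table(path)

    def test_unknown_column_rejected(self, tmp_path):
        df = pd.DataFrame([{c: "" for c in VARIANT_COLUMNS} | {"extra": 1}])
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(TableFormatError, match="extra"):
            read_variant_table(path)

    def test_malformed_hgvs_names_row(self, tmp_path):
        df = pd.DataFrame([{c: "" for c in VARIANT_COLUMNS}])
        df.loc[0, ["gene", "hgvs_p", "consequence", "disease_associated"]] = \
            ["SLC7A9", "p.Xyz1Ala", "missense", "false"]
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(TableFormatError, match="row 1"):
            read_variant_table(path)

    def test_splice_site_rows_use_bare_notation(self, tmp_path):
        df = pd.DataFrame([{c: "" for c in VARIANT_COLUMNS}])
        df.loc[0, ["gene", "hgvs_p", "consequence", "disease_associated"]] = \
            ["SLC3A1", "p.Gly259", "splice_site", "true"]
        path = tmp_path / "v.tsv"
        df.to_csv(path, sep="\t", index=False)
        [record] = read_variant_table(path)
        assert record.mutation.consequence.value == "splice_site"


class TestPatientTable:
    def test_round_trip(self, simulated_files, tmp_path):
        _, path, _, patients = simulated_files
        genotypes, phenotypes = read_patient_table(path)
        assert len(genotypes) == len(patients)
        assert list(phenotypes.index) == list(patients.patient_id)

    def test_both_gene_patient_excluded(self, tmp_path):
        rows = []
        for gene, a1, a2 in [
            ("SLC7A9", "p.Gly105Arg", ""),
            ("SLC3A1", "p.Met467Thr", "p.Thr216fs"),
        ]:
            rows.append({c: "" for c in PATIENT_COLUMNS}
                        | {"patient_id": "DUAL", "gene": gene,
                           "allele1_mutations": a1, "allele2_mutations": a2})
        rows.append({c: "" for c in PATIENT_COLUMNS}
                    | {"patient_id": "OK", "gene": "SLC7A9",
                       "allele1_mutations": "p.Gly105Arg"})
        path = tmp_path / "p.tsv"
        pd.DataFrame(rows, columns=list(PATIENT_COLUMNS)).to_csv(
            path, sep="\t", index=False)
        genotypes, _ = read_patient_table(path)
        assert [g.patient_id for g in genotypes] == ["OK"]

    def test_single_allele_recessive_warned_or_rejected(self, tmp_path):
        row = {c: "" for c in PATIENT_COLUMNS} | {
            "patient_id": "R1", "gene": "SLC3A1",
            "allele1_mutations": "p.Met467Thr"}
        path = tmp_path / "p.tsv"
        pd.DataFrame([row], columns=list(PATIENT_COLUMNS)).to_csv(
            path, sep="\t", index=False)
        genotypes, _ = read_patient_table(path)
        assert genotypes == []
        with pytest.raises(TableFormatError, match="R1"):
            read_patient_table(path, strict_recessive=True)

    def test_malformed_allele_list_names_patient(self, tmp_path):
        row = {c: "" for c in PATIENT_COLUMNS} | {
            "patient_id": "BAD", "gene": "SLC7A9",
            "allele1_mutations": "p.NotAThing"}
        path = tmp_path / "p.tsv"
        pd.DataFrame([row], columns=list(PATIENT_COLUMNS)).to_csv(
            path, sep="\t", index=False)
        with pytest.raises(TableFormatError, match="BAD"):
            read_patient_table(path)


class TestPipeline:
    def test_noiseless_end_to_end_recovers_latent_scores(self, tmp_path):
        config = SimulationConfig(seed=19).noiseless()
        variants, patients = simulate(config)
        write_variant_table(variants, tmp_path / "variants.tsv")
        write_patient_table(patients, tmp_path / "patients.tsv")
        out = run_pipeline(tmp_path / "variants.tsv", tmp_path / "patients.tsv",
                           Method.CADD, tmp_path / "report")
        scores = pd.read_csv(out / "patient_scores.tsv", sep="\t")
        merged = scores.merge(patients[["patient_id", "true_score"]],
                              on="patient_id")
        assert (merged.score == merged.true_score).all()

    def test_rerun_is_byte_identical(self, simulated_files, tmp_path):
        vpath, ppath, _, _ = simulated_files
        out1 = run_pipeline(vpath, ppath, Method.POLYPHEN2, tmp_path / "r1")
        out2 = run_pipeline(vpath, ppath, Method.POLYPHEN2, tmp_path / "r2")
        for name in ("severity_calls.tsv", "patient_scores.tsv",
                     "group_summary.tsv", "comparisons.tsv", "contrast.tsv"):
            assert filecmp.cmp(out1 / name, out2 / name, shallow=False), name

    def test_missing_method_scores_name_mutations(self, simulated_files, tmp_path):
        vpath, ppath, variants, _ = simulated_files
        broken = variants.copy()
        broken["cadd"] = None
        write_variant_table(broken, tmp_path / "broken.tsv")
        with pytest.raises(ValueError, match="cadd.*p\\."):
            run_pipeline(tmp_path / "broken.tsv", ppath, Method.CADD,
                         tmp_path / "r")

    def test_manifest_written_with_inputs(self, simulated_files, tmp_path):
        import json

        vpath, ppath, _, _ = simulated_files
        out = run_pipeline(vpath, ppath, Method.SIFT, tmp_path / "r")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["config"]["method"] == "sift"
        assert len(manifest["inputs"]) == 2
        assert manifest["finished"] >= manifest["started"]


class TestCli:
    def test_simulate_then_run(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        result = runner.invoke(cli_main, [
            "simulate", "--seed", "4", "--out-dir", str(sim_dir)])
        assert result.exit_code == 0, result.output
        assert (sim_dir / "variants.tsv").exists()
        assert (sim_dir / "provenance.json").exists()

        report = tmp_path / "report"
        result = runner.invoke(cli_main, [
            "run", "--variants", str(sim_dir / "variants.tsv"),
            "--patients", str(sim_dir / "patients.tsv"),
            "--method", "polyphen2", "--no-plots",
            "--out-dir", str(report)])
        assert result.exit_code == 0, result.output
        assert (report / "comparisons.tsv").exists()

    def test_contrast_subcommand(self, tmp_path):
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(cli_main, ["simulate", "--seed", "4",
                                 "--out-dir", str(sim_dir)])
        result = runner.invoke(cli_main, [
            "contrast", "--variants", str(sim_dir / "variants.tsv"),
            "--out", str(tmp_path / "contrast.tsv")])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(tmp_path / "contrast.tsv", sep="\t")
        assert set(df.attribute) == {"allele_frequency", "consurf", "ddg"}

    def test_stabilize_threshold_reports_choice(self, tmp_path):
        # noiseless emissions put every mild score at 0.65 and every severe
        # score at 0.92, so the scan is stable across the 0.70-0.90 band
        runner = CliRunner()
        sim_dir = tmp_path / "sim"
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--noiseless",
                                 "--out-dir", str(sim_dir)])
        result = runner.invoke(cli_main, [
            "stabilize-threshold",
            "--variants", str(sim_dir / "variants.tsv"),
            "--patients", str(sim_dir / "patients.tsv"),
            "--method", "polyphen2",
            "--grid-start", "0.70", "--grid-step", "0.05", "--grid-n", "5"])
        assert result.exit_code == 0, result.output
        assert "stable severe threshold" in result.output
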
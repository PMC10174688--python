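"""File formats, model persistence, cohort export and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from fcbrainage.cli import main as cli_main
from fcbrainage.connectivity import ROITimeSeries
from fcbrainage.io import (
    load_model,
    read_motion,
    read_phenotype,
    read_timeseries,
    save_model,
    write_cohort,
    write_motion,
    write_timeseries,
)
from fcbrainage.model import fit_brainage, predict_age


class TestTimeseriesIO:
    def test_round_trip(self, tmp_path, rng):
        ts = ROITimeSeries(values=rng.normal(size=(2, 3)),
                           node_labels=("a", "b", "c"))
        path = tmp_path / "ts.tsv"
        write_timeseries(ts, path)
        back = read_timeseries(path)
        np.testing.assert_allclose(back.values, ts.values, atol=1e-6)
        assert back.node_labels == ts.node_labels

    def test_non_numeric_cell_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\n1.0\t2.0\n1.0\toops\n")
        with pytest.raises(ValueError, match="b"):
            read_timeseries(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_timeseries(path)

    def test_non_reference_parcellation_warns(self, tmp_path, rng):
        ts = ROITimeSeries(values=rng.normal(size=(5, 3)))
        path = tmp_path / "ts.tsv"
        write_timeseries(ts, path)
        with pytest.warns(UserWarning, match="nodes"):
            read_timeseries(path)

    def test_nonzero_mean_warns(self, tmp_path, rng):
        vals = rng.normal(size=(50, 3)) + 100.0
        path = tmp_path / "ts.tsv"
        write_timeseries(ROITimeSeries(values=vals), path)
        with pytest.warns(UserWarning, match="mean"):
            read_timeseries(path)


class TestMotionIO:
    def test_round_trip_and_column_check(self, tmp_path, rng):
        mot = rng.normal(size=(20, 6))
        path = tmp_path / "mot.txt"
        write_motion(mot, path)
        np.testing.assert_allclose(read_motion(path), mot, atol=1e-6)
        bad = tmp_path / "bad.txt"
        np.savetxt(bad, rng.normal(size=(5, 4)))
        with pytest.raises(ValueError, match="6 columns"):
            read_motion(bad)


class TestPhenotype:
    def _write(self, tmp_path, rows):
        path = tmp_path / "pheno.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        return path

    def test_dt_months_from_dates(self, tmp_path):
        path = self._write(tmp_path, [
            dict(subject_id="s1", age_t0=50.0, sex=1,
                 scan_date_t0="2017-06-01", scan_date_t18="2019-03-01"),
            dict(subject_id="s2", age_t0=61.5, sex=0,
                 scan_date_t0="2017-06-15", scan_date_t18="2019-04-20"),
        ])
        df = read_phenotype(path)
        days = (pd.Timestamp("2019-03-01")
                - pd.Timestamp("2017-06-01")).days
        assert df.loc[0, "dt_months"] == pytest.approx(days / 30.4375)

    def test_reversed_dates_rejected(self, tmp_path):
        path = self._write(tmp_path, [
            dict(subject_id="s1", age_t0=50.0, sex=1,
                 scan_date_t0="2019-06-01", scan_date_t18="2017-03-01"),
        ])
        with pytest.raises(ValueError, match="s1"):
            read_phenotype(path)

    def test_duplicate_subject_rejected(self, tmp_path):
        path = self._write(tmp_path, [
            dict(subject_id="s1", age_t0=50.0, sex=1,
                 scan_date_t0="2017-06-01", scan_date_t18="2019-03-01"),
            dict(subject_id="s1", age_t0=51.0, sex=1,
                 scan_date_t0="2017-06-01", scan_date_t18="2019-03-01"),
        ])
        with pytest.raises(ValueError, match="duplicate"):
            read_phenotype(path)

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, [dict(subject_id="s1", age_t0=50.0)])
        with pytest.raises(ValueError, match="missing"):
            read_phenotype(path)


class TestModelPersistence:
    def test_save_load_bit_exact_predictions(self, tmp_path, rng):
        X = rng.normal(size=(20, 6))
        y = rng.uniform(40, 70, 20)
        model = fit_brainage(X, y, edge_index=tuple(
            (i, j) for i in range(4) for j in range(i)
        ))
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(
            predict_age(loaded, X), predict_age(model, X)
        )
        assert loaded.edge_index == model.edge_index

    def test_tampered_json_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="corrupt"):
            load_model(path)
        path.write_text(json.dumps({"schema": "something-else"}))
        with pytest.raises(ValueError, match="fcbrainage-model"):
            load_model(path)

    def test_missing_keys_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text(json.dumps({
            "schema": "fcbrainage-model", "schema_version": 1,
            "weights": [1.0],
        }))
        with pytest.raises(ValueError, match="missing"):
            load_model(path)


class TestCohortExport:
    def test_layout_and_sidecar(self, tmp_path, longitudinal_cohort):
        write_cohort(longitudinal_cohort, tmp_path / "cohort")
        base = tmp_path / "cohort"
        n = longitudinal_cohort.n_subjects
        assert len(list((base / "timeseries").glob("*.tsv"))) == 4 * n
        assert len(list((base / "motion").glob("*.txt"))) == 4 * n
        pheno = pd.read_csv(base / "phenotype.csv")
        assert len(pheno) == n
        assert {"subject_id", "age_t0", "scan_date_t0",
                "scan_date_t18"} <= set(pheno.columns)
        params = json.loads((base / "generator_params.json").read_text())
        assert params["seed"] == longitudinal_cohort.params["seed"]
        # written dates reproduce each subject's interval to <1 day
        parsed = read_phenotype(base / "phenotype.csv")
        dt = np.array([s.dt_months for s in longitudinal_cohort.subjects])
        np.testing.assert_allclose(parsed["dt_months"], dt, atol=0.04)


class TestCli:
    def test_help_exits_zero(self):
        result = CliRunner().invoke(cli_main, ["--help"])
        assert result.exit_code == 0
        assert "simulate" in result.output

    def test_unknown_subcommand_fails(self):
        result = CliRunner().invoke(cli_main, ["frobnicate"])
        assert result.exit_code != 0

    def test_power_subcommand(self):
        result = CliRunner().invoke(
            cli_main, ["power", "--t", "3.66", "--df", "85", "--n", "102"]
        )
        assert result.exit_code == 0
        out = json.loads(result.output)
        assert out["d"] == pytest.approx(0.79, abs=5e-3)
        assert out["r"] == pytest.approx(0.369, abs=5e-4)
        assert round(100 * out["beta"]) == 3
        assert out["n_required"] == 90

    def test_missing_input_path_fails(self, tmp_path):
        result = CliRunner().invoke(cli_main, [
            "train", "--features", str(tmp_path / "nope.tsv"),
            "--phenotype", str(tmp_path / "nope.csv"),
            "--model-out", str(tmp_path / "m.json"),
        ])
        assert result.exit_code != 0

    def test_end_to_end_simulate_fc_train_predict(self, tmp_path):
        """Smoke pipeline: simulate a tiny cohort on disk, build features
        for one session, train, and predict."""
        runner = CliRunner()
        outdir = tmp_path / "cohort"
        res = runner.invoke(cli_main, [
            "simulate", "--n-subjects", "8", "--n-nodes", "10",
            "--frames-per-run", "60", "--seed", "3",
            "--out", str(outdir),
        ])
        assert res.exit_code == 0, res.output
        # session features for every subject via the library, then the
        # train/predict commands on the resulting table
        import fcbrainage as fb
        feats = {}
        for sid in pd.read_csv(outdir / "phenotype.csv")["subject_id"]:
            runs = [read_timeseries(outdir / "timeseries"
                                    / f"{sid}_T0_run-{r}.tsv")
                    for r in (1, 2)]
            motions = [read_motion(outdir / "motion"
                                   / f"{sid}_T0_run-{r}.txt")
                       for r in (1, 2)]
            ev, _ = fb.session_edge_features(runs, motions)
            feats[sid] = ev.values
        cols = [f"{i}_{j}" for i, j in ev.edge_index]
        fpath = tmp_path / "features.tsv"
        pd.DataFrame.from_dict(feats, orient="index",
                               columns=cols).to_csv(fpath, sep="\t")
        res = runner.invoke(cli_main, [
            "train", "--features", str(fpath),
            "--phenotype", str(outdir / "phenotype.csv"),
            "--k-folds", "4", "--model-out", str(tmp_path / "m.json"),
        ])
        assert res.exit_code == 0, res.output
        res = runner.invoke(cli_main, [
            "predict", "--model", str(tmp_path / "m.json"),
            "--features", str(fpath),
            "--out", str(tmp_path / "pred.csv"),
        ])
        assert res.exit_code == 0, res.output
        pred = pd.read_csv(tmp_path / "pred.csv")
        assert len(pred) == 8
        assert np.all(np.isfinite(pred["predicted_age"]))


class TestExclusionLedger:
    def test_counts_balance_with_reasons(self, small_model):
        """n_input = n_included + n_excluded, every exclusion tagged."""
        from fcbrainage.pipeline import cohort_feature_table
        from fcbrainage.synthetic import simulate_cohort_t0
        # high spike rate so some subjects fail the retention gate
        cohort = simulate_cohort_t0(
            12, model=small_model, frames_per_run=80, seed=21,
            spike_prob=0.12,
        )
        feats, ledger, _ = cohort_feature_table(cohort, "t0")
        assert len(ledger) == 12
        n_inc = int(ledger["included"].sum())
        assert n_inc == len(feats)
        excluded = ledger[~ledger["included"]]
        assert len(excluded) == 12 - n_inc
        assert (excluded["reason"] == "retention_below_threshold").all()
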
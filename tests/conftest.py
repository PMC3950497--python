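import base64

import numpy as np
import pytest
from hypothesis import settings

from srmpk import ChromatogramSimConfig, load_study_concentrations

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def noiseless_config():
    """Chromatogram simulation with no baseline noise and no RT jitter."""
    return ChromatogramSimConfig(
        baseline_rms=0.0,
        retention_time_jitter_sd=0.0,
        response_slope=100.0,
        transition_relative_intensities=(0.5, 0.3, 0.2),
        seed=1,
    )


@pytest.fixture(scope="session")
def study_profiles():
    return load_study_concentrations()


@pytest.fixture(scope="session")
def profile_by_animal(study_profiles):
    return {p.animal_id: p for p in study_profiles}


def _b64(arr):
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode()


def make_mzml(path, chromatograms, time_unit="second"):
    """Write a minimal mzML file with the given SRM chromatograms.

    ``chromatograms`` is a list of (q1, q3, times, intensities).
    """
    parts = []
    for index, (q1, q3, times, intens) in enumerate(chromatograms):
        t64, i64 = _b64(times), _b64(intens)
        parts.append(f"""
      <chromatogram id="SRM SIC Q1={q1} Q3={q3}" index="{index}" defaultArrayLength="{len(times)}">
        <precursor><isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q1}"/>
        </isolationWindow></precursor>
        <product><isolationWindow>
            <cvParam cvRef="MS" accession="MS:1000827" name="isolation window target m/z" value="{q3}"/>
        </isolationWindow></product>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(t64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000595" name="time array" unitAccession="UO:0000010" unitName="{time_unit}"/>
            <binary>{t64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(i64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>
            <binary>{i64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </chromatogram>""")
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1"><chromatogramList count="{len(chromatograms)}">{''.join(parts)}
  </chromatogramList></run>
</mzML>
"""
    path.write_text(doc)
    return path


def make_mzml_spectra_only(path):
    """An mzML file with an MS1 spectrum and no chromatogram list."""
    path.write_text("""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <run id="r1"><spectrumList count="1">
    <spectrum id="scan=1" index="0" defaultArrayLength="0">
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum"/>
    </spectrum>
  </spectrumList></run>
</mzML>
""")
    return path
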
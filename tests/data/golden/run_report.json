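{
  "config_sha256": "aed6c506bf408ec1",
  "outputs": {
    "counts": {
      "path": "simulated/counts.tsv",
      "sha256": "fc1e2fcea2badff99aa8e579b93810162248d0c62d8db9f467d7ddcd01cedd25"
    },
    "counts_truth": {
      "path": "simulated/counts.tsv.truth.tsv",
      "sha256": "657ab34f8dcee13d16e442fb038d7cb9126581d2634c7c2df82b4c99e1b0cec0"
    },
    "cytokine_corrected": {
      "path": "cytokine_corrected.tsv",
      "sha256": "e90da863429a51f941970a00a75de2a08080e204b0665d523ea773d4a620f886"
    },
    "flux_metrics": {
      "path": "flux_metrics.tsv",
      "sha256": "b9eb501351a02000eee165103dc2de50aa923bde518b4124b48ef94676de03c0"
    },
    "flux_trace": {
      "path": "simulated/flux_trace.tsv",
      "sha256": "3364f15de24c82088f98453b1e9a628813d29bef82786f573448147dc078b2f0"
    },
    "flux_truth": {
      "path": "simulated/flux_trace.tsv.truth.tsv",
      "sha256": "dab1fa0941d97dc68ec79e3c384d0165cb1f8984454fc37415c39fd37c59c4f8"
    },
    "groups": {
      "path": "simulated/groups.tsv",
      "sha256": "4fd751a8900bfdbbd36a0302d4403d3157fd95714b6503eab1b952317a197414"
    },
    "mids": {
      "path": "mids.tsv",
      "sha256": "5630ec08795e6ac2c53cf04d8ab5c5bcee37cd8aa720b7fd14a21bed7aefe268"
    },
    "plate": {
      "path": "simulated/plate.csv",
      "sha256": "4678718fc03985910d7a9fcd4f4d5c970f702f8a6f1e9fd8890b11f4e8d441d8"
    },
    "plate_truth": {
      "path": "simulated/plate.csv.truth.tsv",
      "sha256": "63eb2359f89740e2026346d25004cfa52c2b4c79006abf7fb86da450c758ee14"
    },
    "signature_comparison": {
      "path": "signature_comparison.json",
      "sha256": "cdb40e30d2f47be666af8664e23905a041880c4a565504c95f2f24cd626250a3"
    },
    "signature_genes": {
      "path": "simulated/signature_genes.txt",
      "sha256": "60c26f769571ddf89522d232df7cd0810b4950b5568767e19695572d88ba372b"
    },
    "signature_scores": {
      "path": "signature_scores.tsv",
      "sha256": "f41a90e4ccde39a53c50e3f14578d151bfb217bb409fe282d699d579f760b14a"
    },
    "spectra": {
      "path": "simulated/spectra.tsv",
      "sha256": "59170bbd2fb2eaa8f5c2800718078de82b9e9fdafe2cd946c6d7dc3a197f28ff"
    },
    "spectra_truth": {
      "path": "simulated/spectra.tsv.truth.tsv",
      "sha256": "c4a12eb074ee137e8fbce25f8d83e09213985aedd0f6a525d24ef7306ec5dab3"
    }
  },
  "seed": 11,
  "stages": [
    "simulate",
    "mid_correct",
    "flux",
    "signature",
    "cytokine"
  ],
  "version": "0.1.0"
}
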
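{
  "dfi_panel_counts.csv": {
    "sha256": "63d791fbfd18590e04fd03c4591ff1d72da2a26b0dd12dcdb3cd7ba20cc2b18d",
    "rows": 7
  },
  "gcms_counts.csv": {
    "sha256": "d227790df6cd71bb13eb867410f4ad336d3dd0434b387436f5f57d200205ff80",
    "rows": 3
  },
  "lipid_class_counts.csv": {
    "sha256": "7a91c5ac54e632d6c91e116afe2d430daeb75941a49295ed01328300783a2663",
    "rows": 7
  },
  "platform_counts.csv": {
    "sha256": "8f5c7d987f9b4e38deeaa597b96d5fbaaa99ee42939f91f5a6b26b26723bac68",
    "rows": 7
  },
  "synonyms.csv": {
    "sha256": "a2862bcd0db41ceb6e0a04bd71ed4bc381b1df9f78db02c2f778375651403a5e",
    "rows": 4
  },
  "table03_nmr.csv": {
    "sha256": "ada3829e5743b8a7288c8bfa4c09c4cdcf4b22952623c1900cb4a5c161e0311c",
    "rows": 50
  },
  "table04_gcms_global.csv": {
    "sha256": "6f1999657dd1649bda9af8eafcd27113397370a2cae6863f06d693fd4e77f8b0",
    "rows": 74
  },
  "table05_ffa_targeted.csv": {
    "sha256": "f0d8d37b07836544a8b20ddd73deed837012ad38a764ca79a7b708e7fb0d8f76",
    "rows": 25
  },
  "table06_gcms_quantified.csv": {
    "sha256": "46206880f991acf33e7c3f2f7041daaf546616219e03b705e7e6fab9ea497348",
    "rows": 14
  },
  "table07_oxylipins_n6.csv": {
    "sha256": "8d447525a881517835369a65b4a1bc086576f93446ee3c1bb0cec6e1a89fd1f4",
    "rows": 40
  },
  "table08_oxylipins_n3.csv": {
    "sha256": "5c9b3d450ab708a432aa1c89d4fcf5e240a940a1055e384b14a3d8b85ccb836f",
    "rows": 15
  },
  "table09_oxylipins_c18.csv": {
    "sha256": "222a3b6cc9128ecf99ea688520df89774222128fc00f98adfd66e00edd8bf95f",
    "rows": 21
  },
  "table10_acyl_amides_glycerols.csv": {
    "sha256": "7f35631df601f87025ec9e02cc64fd7f303dc8a7473a399d503d7104d0b0e9d9",
    "rows": 20
  },
  "table11_lipomics.csv": {
    "sha256": "8662f4a7cf45a6f0f88d5bc7b4dd75885015a365d348ba782133ceebf7789db0",
    "rows": 32
  },
  "table12_dfi.csv": {
    "sha256": "0c939df6c0055ca6af7d2c3df8937ebe1c387d207fec665ed2f9ed6aa6739dbd",
    "rows": 39
  },
  "table13_dfi_lipids.csv": {
    "sha256": "4b05af9f45cbafbdf56abfd930fb82a784d7c84252e6d1f077fb821b7fe00495",
    "rows": 27
  },
  "table14_lysopc_comparison.csv": {
    "sha256": "a2c52e8cf57f51d4fbc01be7cabd4a2574de34a0e469b39833bb03fbbf1f64f4",
    "rows": 16
  }
}
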
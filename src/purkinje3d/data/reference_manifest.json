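{
 "seed": 7,
 "checksums": {
  "ellipsoid_phase": "956a0e3fecdb317cc13b714ad4a036c4438d4acac73716232054058f4fcb54e8",
  "cylinder_phase": "abbbb8e0352452d9dcb0852978e699a7e96a9c996cc47c328f48513942c301cb",
  "network_mask": "6687ea3d6e1195be5f1cbbc7796811747095cb368eb1c6481c39b152032e7b37",
  "network_sites": "1c420617d7ce78baf8108ab662c0a3a4553edebbfa0114188db325f59eb56af2",
  "curve_ellipsoid": "631b4dbeb0143cbdd3f3c6de8ca9472a76dd4f77f5dad9d2498a27cafd41e06b",
  "curve_cylinder": "5a9a8a9dca38140f409681fba970f37bcabba51830dbc8d0f89f16bc5dd422e1"
 }
}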
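{
 "dcxmt_version": "0.1.0",
 "files": {
  "mutations_10.csv": "5e033ebbc2c4d6c5c4bf32876d8fae6b600b32680add2228ee747d7e74dc52d5",
  "stack_11pf.mrc": "cf8db36943e17ce88b1fe3e99206d696bad62384bba262f5973729d383c7ad2a",
  "stack_11pf.mrc.json": "5eac2df44b93e8b7dcf94ce2aef58521127f9b65e224ad80e105b9423426aa80",
  "stack_12pf.mrc": "b617bc7c79a73bc0958d62f311fbf149ec71fa7657b4290ea03dcd53c26b2c3a",
  "stack_12pf.mrc.json": "77b96e80318221672d4fc9ffe307d7bbaea97b4675b271d5bd95bdb572d258ba",
  "stack_13pf.mrc": "9cfc7a1ea55b5cd4c2abaf89307ec4ee3fc16b99edcdd41aa586b2c73fff01d1",
  "stack_13pf.mrc.json": "e0967b4017d0deb0892c4e7d6583e5af8235ec1bfcecb51eba2ac22a712afee4",
  "stack_14pf.mrc": "114189397a5f305386fe6a6394d10ce3b3998e00a47380fa261326490aa7c353",
  "stack_14pf.mrc.json": "f6502c4fe590f520e137d389c295cef96e86dc8637259e1ce17e2812d891eb46",
  "stack_15pf.mrc": "1831a1ca326395f7c8b9e6913d85a1762938ca2506f27e13698047c033003c6d",
  "stack_15pf.mrc.json": "611b07438ed60572fcc7099ddb4a17e21cb1beef3ab1d169e83cd2783ef1a876",
  "stack_16pf.mrc": "f7e5eb587ce88771a3df9eae2866e1520e8444d987d86ab37486b6eee230c8ab",
  "stack_16pf.mrc.json": "e51348207185e24bd12650196ead5dc6ad8b180c67619884fcdfff8a3266d920",
  "toy_complex.pdb": "b14b2504538bcf30d01d44f14a0fb2a2782f44e63b900eba58c1fe98f97b05d1",
  "toy_domain.pdb": "982162d1db21870b355ba6a60392c3a7424255b3822a67fae14d45ce65327d75"
 },
 "seed": 0
}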
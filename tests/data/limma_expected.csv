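gene,logfc,t,p
g00,0.899433173562816,2.34412059887261,0.0280167514647192
g01,1.08970758960934,2.42902591935035,0.0233057473923983
g02,1.25752329835962,3.04511946480238,0.00571989253900793
g03,1.36470529996503,3.22833990990084,0.00369738427372011
g04,2.05196110631438,5.80870655113626,6.27165976865635e-06
g05,1.52715360676421,3.39659844763617,0.00246308888706151
g06,1.36572224423524,3.48350694254902,0.00199340284688485
g07,2.05094835241804,5.4924439504475,1.35680880200085e-05
g08,2.43126307677994,6.267203721803,2.0854914475587e-06
g09,0.819173478095719,2.03199718330559,0.0537841874500516
g10,1.17217660070802,2.46845008147666,0.0213772195265163
g11,1.28351643512056,3.38802243639128,0.00251489998654094
g12,0.207377062455193,0.52998910374377,0.601166648224254
g13,-0.358590853846941,-0.952925813236412,0.350472927156033
g14,-0.0079635901423632,-0.0151111504852373,0.988072992249496
g15,0.605138008961996,1.66296984912636,0.109800886908993
g16,0.679064089089456,1.76634573383867,0.0905239622504245
g17,-0.322241297138975,-0.713321334690977,0.482776991493624
g18,-0.083680996362929,-0.184613859491939,0.855139757576226
g19,-0.525808601631942,-1.38787897072763,0.178388959598147
g20,0.644625406263982,1.53616562134457,0.138054602397478
g21,-0.674985368048502,-1.38556431778759,0.17908602728884
g22,0.422821166924093,1.12857029388263,0.270640125828974
g23,-0.269787226432769,-0.717057694539835,0.480511860747062
g24,0.77619221316117,1.88270055292419,0.0723693579867586
g25,-0.519354524881591,-0.91865152599928,0.36775151431634
g26,0.211154185980788,0.507989461823372,0.6162673632021
g27,0.269867318349829,0.642432377156223,0.526904602712558
g28,0.642723859970898,1.25559561339908,0.221789241272125
g29,0.840727877606892,1.52076050582603,0.141862993171541
g30,0.157896773224302,0.445537950612277,0.660070009914897
g31,0.160669786740873,0.355351714478257,0.725543661277143
g32,0.0305932829740713,0.0686599350994107,0.945849960839254
g33,0.255475062907168,0.65561207902654,0.518537163333979
g34,-0.512550982667945,-0.973885530901937,0.340181148041505
g35,0.926125539899899,2.47406204047728,0.0211150498326305
g36,0.652827869365058,1.88403440433855,0.0721810951052824
g37,0.314283627867595,0.727908005257298,0.47396907696137
g38,0.776401630373059,1.86285287976065,0.0752217051815071
g39,0.132249107862848,0.311945682695892,0.757874231432691
g40,-0.636205749563326,-1.51465741809992,0.143395372218
g41,-0.0917227291159787,-0.204830248691407,0.83949512842703
g42,-0.825304361716734,-1.50215224381461,0.146577466455806
g43,-0.475108246051909,-1.19100718007408,0.245720466401737
g44,-0.486328162912754,-1.20712549528964,0.23957443455267
g45,0.0144475472061589,0.0317780744141212,0.974921442984105
g46,-0.611976062517527,-1.21280342421056,0.237437129477765
g47,-1.39738152825322,-2.6590041737292,0.0139771449939349
g48,0.165051170808456,0.437968038411832,0.665469099957129
g49,0.077244837435179,0.185420403135095,0.854514397070777
g50,0.107943760152929,0.228065785268065,0.821597633895307
g51,0.350927010580977,0.623535518283427,0.539028746541881
g52,0.504937759843998,0.957968723416815,0.347977682111434
g53,-0.587500382796096,-1.56043892890491,0.132224587585432
g54,-0.770024544342096,-2.12087082167828,0.044856077647066
g55,-0.742473224740115,-1.8485036087244,0.0773443198525792
g56,-0.00336229387179863,-0.00787665060988903,0.993782896322387
g57,0.177755640231392,0.524525527011396,0.604900251902814
g58,-0.0161421086701496,-0.0394704053308453,0.968853792153198
g59,0.948468542232765,1.8791875283267,0.0728672453551946
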
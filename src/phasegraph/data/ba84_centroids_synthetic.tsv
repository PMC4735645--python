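label	x	y	z
BA01_L	-45.0	-26.0	50.0
BA01_R	45.0	-26.0	50.0
BA02_L	-42.0	-30.0	48.0
BA02_R	42.0	-30.0	48.0
BA03_L	-38.0	-24.0	52.0
BA03_R	38.0	-24.0	52.0
BA04_L	-38.0	-18.0	52.0
BA04_R	38.0	-18.0	52.0
BA05_L	-18.0	-44.0	60.0
BA05_R	18.0	-44.0	60.0
BA06_L	-28.0	-2.0	54.0
BA06_R	28.0	-2.0	54.0
BA07_L	-18.0	-62.0	54.0
BA07_R	18.0	-62.0	54.0
BA08_L	-24.0	26.0	46.0
BA08_R	24.0	26.0	46.0
BA09_L	-30.0	36.0	32.0
BA09_R	30.0	36.0	32.0
BA10_L	-24.0	56.0	8.0
BA10_R	24.0	56.0	8.0
BA11_L	-20.0	42.0	-16.0
BA11_R	20.0	42.0	-16.0
BA13_L	-38.0	-4.0	6.0
BA13_R	38.0	-4.0	6.0
BA17_L	-12.0	-84.0	4.0
BA17_R	12.0	-84.0	4.0
BA18_L	-20.0	-88.0	8.0
BA18_R	20.0	-88.0	8.0
BA19_L	-32.0	-80.0	16.0
BA19_R	32.0	-80.0	16.0
BA20_L	-48.0	-24.0	-26.0
BA20_R	48.0	-24.0	-26.0
BA21_L	-56.0	-24.0	-10.0
BA21_R	56.0	-24.0	-10.0
BA22_L	-54.0	-24.0	4.0
BA22_R	54.0	-24.0	4.0
BA23_L	-6.0	-38.0	28.0
BA23_R	6.0	-38.0	28.0
BA24_L	-6.0	8.0	34.0
BA24_R	6.0	8.0	34.0
BA25_L	-6.0	18.0	-10.0
BA25_R	6.0	18.0	-10.0
BA27_L	-14.0	-34.0	2.0
BA27_R	14.0	-34.0	2.0
BA28_L	-20.0	-12.0	-24.0
BA28_R	20.0	-12.0	-24.0
BA29_L	-8.0	-46.0	12.0
BA29_R	8.0	-46.0	12.0
BA30_L	-14.0	-52.0	10.0
BA30_R	14.0	-52.0	10.0
BA31_L	-10.0	-54.0	34.0
BA31_R	10.0	-54.0	34.0
BA32_L	-8.0	32.0	22.0
BA32_R	8.0	32.0	22.0
BA33_L	-4.0	6.0	22.0
BA33_R	4.0	6.0	22.0
BA34_L	-20.0	0.0	-16.0
BA34_R	20.0	0.0	-16.0
BA35_L	-22.0	-24.0	-16.0
BA35_R	22.0	-24.0	-16.0
BA36_L	-30.0	-32.0	-16.0
BA36_R	30.0	-32.0	-16.0
BA37_L	-44.0	-54.0	-12.0
BA37_R	44.0	-54.0	-12.0
BA38_L	-36.0	14.0	-28.0
BA38_R	36.0	14.0	-28.0
BA39_L	-44.0	-62.0	30.0
BA39_R	44.0	-62.0	30.0
BA40_L	-52.0	-40.0	38.0
BA40_R	52.0	-40.0	38.0
BA41_L	-46.0	-26.0	10.0
BA41_R	46.0	-26.0	10.0
BA42_L	-58.0	-24.0	10.0
BA42_R	58.0	-24.0	10.0
BA43_L	-54.0	-12.0	16.0
BA43_R	54.0	-12.0	16.0
BA44_L	-50.0	12.0	16.0
BA44_R	50.0	12.0	16.0
BA45_L	-50.0	28.0	10.0
BA45_R	50.0	28.0	10.0
BA46_L	-44.0	38.0	18.0
BA46_R	44.0	38.0	18.0
BA47_L	-40.0	28.0	-12.0
BA47_R	40.0	28.0	-12.0
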
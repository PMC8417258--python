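miniIGH	2000	2295	IGHV1-2|V	0	+
miniIGH	4295	4590	IGHV2-5|V	0	+
miniIGH	6590	6885	IGHV3-23|V	0	+
miniIGH	8885	9180	IGHV4-34|V	0	+
miniIGH	11180	11475	IGHV5-51|V	0	+
miniIGH	13475	13770	IGHV6-1|V	0	+
miniIGH	15770	16065	IGHV7-4|V	0	+
miniIGH	18065	18360	IGHV1-69|V	0	+
miniIGH	18860	18886	IGHD2-2|D	0	+
miniIGH	19386	19416	IGHD3-10|D	0	+
miniIGH	19916	19930	IGHD5-18|D	0	+
miniIGH	20430	20478	IGHJ4|J	1	+
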
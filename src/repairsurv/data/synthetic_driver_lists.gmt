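aml	synthetic placeholder driver list	TP53	DRV00_01	DRV00_02	DRV00_03	DRV00_04	DRV00_05	DRV00_06	DRV00_07	DRV00_08	DRV00_09	DRV00_10	DRV00_11	DRV00_12	DRV00_13	DRV00_14	DRV00_15	DRV00_16	DRV00_17	DRV00_18	DRV00_19
bladder	synthetic placeholder driver list	TP53	DRV01_01	DRV01_02	DRV01_03	DRV01_04	DRV01_05	DRV01_06	DRV01_07	DRV01_08	DRV01_09	DRV01_10	DRV01_11	DRV01_12	DRV01_13	DRV01_14	DRV01_15	DRV01_16	DRV01_17	DRV01_18	DRV01_19
brainlgg	synthetic placeholder driver list	TP53	DRV02_01	DRV02_02	DRV02_03	DRV02_04	DRV02_05	DRV02_06	DRV02_07	DRV02_08	DRV02_09	DRV02_10	DRV02_11	DRV02_12	DRV02_13	DRV02_14	DRV02_15	DRV02_16	DRV02_17	DRV02_18	DRV02_19
gbm	synthetic placeholder driver list	TP53	DRV03_01	DRV03_02	DRV03_03	DRV03_04	DRV03_05	DRV03_06	DRV03_07	DRV03_08	DRV03_09	DRV03_10	DRV03_11	DRV03_12	DRV03_13	DRV03_14	DRV03_15	DRV03_16	DRV03_17	DRV03_18	DRV03_19
headneck	synthetic placeholder driver list	TP53	DRV04_01	DRV04_02	DRV04_03	DRV04_04	DRV04_05	DRV04_06	DRV04_07	DRV04_08	DRV04_09	DRV04_10	DRV04_11	DRV04_12	DRV04_13	DRV04_14	DRV04_15	DRV04_16	DRV04_17	DRV04_18	DRV04_19
sarcoma	synthetic placeholder driver list	TP53	DRV05_01	DRV05_02	DRV05_03	DRV05_04	DRV05_05	DRV05_06	DRV05_07	DRV05_08	DRV05_09	DRV05_10	DRV05_11	DRV05_12	DRV05_13	DRV05_14	DRV05_15	DRV05_16	DRV05_17	DRV05_18	DRV05_19
breast	synthetic placeholder driver list	TP53	DRV06_01	DRV06_02	DRV06_03	DRV06_04	DRV06_05	DRV06_06	DRV06_07	DRV06_08	DRV06_09	DRV06_10	DRV06_11	DRV06_12	DRV06_13	DRV06_14	DRV06_15	DRV06_16	DRV06_17	DRV06_18	DRV06_19
cervical	synthetic placeholder driver list	TP53	DRV07_01	DRV07_02	DRV07_03	DRV07_04	DRV07_05	DRV07_06	DRV07_07	DRV07_08	DRV07_09	DRV07_10	DRV07_11	DRV07_12	DRV07_13	DRV07_14	DRV07_15	DRV07_16	DRV07_17	DRV07_18	DRV07_19
colorectal	synthetic placeholder driver list	TP53	DRV08_01	DRV08_02	DRV08_03	DRV08_04	DRV08_05	DRV08_06	DRV08_07	DRV08_08	DRV08_09	DRV08_10	DRV08_11	DRV08_12	DRV08_13	DRV08_14	DRV08_15	DRV08_16	DRV08_17	DRV08_18	DRV08_19
liver	synthetic placeholder driver list	TP53	DRV09_01	DRV09_02	DRV09_03	DRV09_04	DRV09_05	DRV09_06	DRV09_07	DRV09_08	DRV09_09	DRV09_10	DRV09_11	DRV09_12	DRV09_13	DRV09_14	DRV09_15	DRV09_16	DRV09_17	DRV09_18	DRV09_19
lung	synthetic placeholder driver list	TP53	DRV10_01	DRV10_02	DRV10_03	DRV10_04	DRV10_05	DRV10_06	DRV10_07	DRV10_08	DRV10_09	DRV10_10	DRV10_11	DRV10_12	DRV10_13	DRV10_14	DRV10_15	DRV10_16	DRV10_17	DRV10_18	DRV10_19
lungsc	synthetic placeholder driver list	TP53	DRV11_01	DRV11_02	DRV11_03	DRV11_04	DRV11_05	DRV11_06	DRV11_07	DRV11_08	DRV11_09	DRV11_10	DRV11_11	DRV11_12	DRV11_13	DRV11_14	DRV11_15	DRV11_16	DRV11_17	DRV11_18	DRV11_19
melanoma	synthetic placeholder driver list	TP53	DRV12_01	DRV12_02	DRV12_03	DRV12_04	DRV12_05	DRV12_06	DRV12_07	DRV12_08	DRV12_09	DRV12_10	DRV12_11	DRV12_12	DRV12_13	DRV12_14	DRV12_15	DRV12_16	DRV12_17	DRV12_18	DRV12_19
ovarian	synthetic placeholder driver list	TP53	DRV13_01	DRV13_02	DRV13_03	DRV13_04	DRV13_05	DRV13_06	DRV13_07	DRV13_08	DRV13_09	DRV13_10	DRV13_11	DRV13_12	DRV13_13	DRV13_14	DRV13_15	DRV13_16	DRV13_17	DRV13_18	DRV13_19
rcc	synthetic placeholder driver list	TP53	DRV14_01	DRV14_02	DRV14_03	DRV14_04	DRV14_05	DRV14_06	DRV14_07	DRV14_08	DRV14_09	DRV14_10	DRV14_11	DRV14_12	DRV14_13	DRV14_14	DRV14_15	DRV14_16	DRV14_17	DRV14_18	DRV14_19
rpc	synthetic placeholder driver list	TP53	DRV15_01	DRV15_02	DRV15_03	DRV15_04	DRV15_05	DRV15_06	DRV15_07	DRV15_08	DRV15_09	DRV15_10	DRV15_11	DRV15_12	DRV15_13	DRV15_14	DRV15_15	DRV15_16	DRV15_17	DRV15_18	DRV15_19
stomach	synthetic placeholder driver list	TP53	DRV16_01	DRV16_02	DRV16_03	DRV16_04	DRV16_05	DRV16_06	DRV16_07	DRV16_08	DRV16_09	DRV16_10	DRV16_11	DRV16_12	DRV16_13	DRV16_14	DRV16_15	DRV16_16	DRV16_17	DRV16_18	DRV16_19
uterine	synthetic placeholder driver list	TP53	DRV17_01	DRV17_02	DRV17_03	DRV17_04	DRV17_05	DRV17_06	DRV17_07	DRV17_08	DRV17_09	DRV17_10	DRV17_11	DRV17_12	DRV17_13	DRV17_14	DRV17_15	DRV17_16	DRV17_17	DRV17_18	DRV17_19
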
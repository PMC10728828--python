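model_name,task_type,n_params,n_layers,device_name,kwh_per_1e7_tiles
MobileNetV2,classification,3538984,88,quadro_6000,0.461
MobileNetV3Small,classification,2554968,88,quadro_6000,0.4819
EfficientNetB0,classification,5330571,132,quadro_6000,1.9526
EfficientNetB3,classification,12320535,210,quadro_6000,1.761
EfficientNetB7,classification,66658687,438,quadro_6000,9.3326
EfficientNetV2L,classification,119362131,479,quadro_6000,13.3582
NASNetMobile,classification,5326716,389,quadro_6000,1.3017
NASNetLarge,classification,88949818,533,quadro_6000,24.8336
DenseNet121,classification,8062504,121,quadro_6000,1.3301
DenseNet201,classification,20242984,201,quadro_6000,1.0392
ResNet50,classification,25636712,107,quadro_6000,4.5569
ResNet152,classification,60419944,311,quadro_6000,9.0533
InceptionV3,classification,23851784,159,quadro_6000,3.2869
InceptionResNetV2,classification,55873736,449,quadro_6000,7.0598
Xception,classification,22910480,126,quadro_6000,4.6163
VGG16,classification,138357544,16,quadro_6000,13.55
VGG19,classification,143667240,19,quadro_6000,9.6199
ConvNeXtTiny,classification,28589128,53,quadro_6000,4.9415
ConvNeXtBase,classification,88591464,85,quadro_6000,5.9856
ConvNeXtXLarge,classification,350196968,97,quadro_6000,22.242
UNet-2D,segmentation,31030593,49,quadro_6000,4.9108
UNetPlusPlus,segmentation,36629633,70,quadro_6000,2.4181
AttentionUNet,segmentation,34877745,58,quadro_6000,12.9084
ResUNet,segmentation,32461057,66,quadro_6000,4.9002
DeepLabV3Plus,segmentation,41253890,91,quadro_6000,3.8601
FPN,segmentation,23911522,78,quadro_6000,2.2431
LinkNet,segmentation,20324562,61,quadro_6000,3.0681
PSPNet,segmentation,24298882,55,quadro_6000,2.3378
TransUNet,segmentation,105277081,112,quadro_6000,7.5274
SwinUNet,segmentation,27166905,87,quadro_6000,9.7493
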